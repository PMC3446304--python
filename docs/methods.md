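# Methods

## The measurement model

After rifampicin blocks transcription initiation, each mRNA species decays
(approximately) by first-order kinetics, N(t) = N₀·2^(−t/t½). RNA-Seq
coverage of a gene at chase time t is proportional to N(t) — but only up to
an unknown per-sample scale: libraries are prepared from comparable amounts
of cDNA and sequenced to a roughly fixed read budget, so the bulk decay of
the mRNA pool, depletion-efficiency differences, and lane-to-lane variation
all distort the proportionality constant per sample. Absolute decay is
therefore unidentifiable from coverage alone; the pipeline restores the
time axis with anchor genes whose half-lives are measured independently by
RT-qPCR against 16S rRNA (which is stable over a 10-minute chase).

For each anchor g and time t > 0 the expected abundance is
RPK(g,0)·2^(−t/t½_qPCR(g)); the per-time-point normalization factor is the
geometric mean over anchors of expected/observed. The geometric mean is the
right average here because the component factors are ratios spanning
different abundance scales: it weighs down outliers and makes the log
residuals of the anchors sum exactly to zero at every time point (a
property the test suite asserts to 1e-9). Factors multiply observed
post-arrest RPK values; t0 is the reference and is never rescaled.

## Half-life estimation

Per-gene RPK series (reads estimated as per-base coverage summed over the
CDS divided by the read length; RPK = reads × 1000 / CDS length) are fitted
by ordinary least squares of ln(RPK) on t. R² of this log-linear fit is the
fit-quality statistic; a linear-scale R² is also computed for sensitivity,
and a nonlinear least-squares fit (N₀·e^(−kt) on the linear scale) is
available via `fit_decay(..., method="nls")`. Exclusion rules, applied in
order: t0 expression < 50 RPK (strict); more than one missing post-arrest
point, where a zero RPK counts as missing (the data cannot distinguish zero
from absent); log-scale R² < 0.8 (strict). Surviving fits with t½ > 15 min
or k ≤ 0 are reported at 15 min with a `capped` flag: beyond that horizon a
10-minute chase has essentially no leverage, and an increasing series is
indistinguishable from noise around a stable transcript. Capped values
enter all order statistics at 15.

## Transcriptional units

TUs are called from coverage pooled over all samples. A maximal run of
non-zero coverage is a candidate; it is retained iff its mean coverage is
strictly above 5 reads/bp (the threshold applies to the stretch average,
not per base). Retained stretches separated by ≤ 5 bp of zero coverage are
fused, and the fused unit's mean is recomputed over its full span. Adjacent
TUs whose facing ends both fall inside one region coverable only by
non-unique 52-mers (both strands considered; reverse-complement matches
count) are fused, iterating to fixpoint — such regions are exactly where
52-nt reads cannot be placed, so an apparent coverage gap there is not
evidence of two transcripts. Fusion order is threshold → gap-fuse →
k-mer-fuse; the mean threshold is not re-applied after fusing.

Gene association: single-strand TUs become oriented transcribed regions;
TU boundaries inside a member CDS raise `TSS_inside_gene` /
`TES_inside_gene`; mixed-strand TUs are split at every strand junction
(convergent junctions put each fragment's TES at its block's annotated gene
stop, divergent junctions put each TSS at the annotated gene start — note
any opposite-strand junction is one or the other). UTR lengths are only
reported where the corresponding boundary was observed from coverage, not
set by a flag or a split.

A note on monotonicity: raising the gap-fusing distance can only reduce the
TU count, but raising the mean-coverage threshold can *increase* it when
fusing is active (removing a weak middle stretch may break a fused chain in
two). The property tests reflect this: merge-gap monotonicity is asserted
unconditionally, mean-threshold monotonicity only with fusing disabled.

## Decay directionality

For every TU with mean t0 coverage ≥ 50 reads/bp, per-base profiles of
log2((cov_t × f_t)/cov_t0) are computed; bases with zero coverage at either
end of the ratio are masked rather than pseudocounted, because rank
statistics are sensitive to imputed floors (plots use a 1-read pseudocount
so curves stay finite, but the statistics never see it). Direction is
classified per ORF, not per TU — segmental operons would otherwise mask
per-gene behaviour — by Spearman's rho between the t10 log2 ratio and the
distance from the ORF start measured in the direction of transcription
(so the statistic is strand-correct by construction, and reversing the
axis negates rho exactly). rho > 0.3 with P < 0.0005 (two-sided
t-approximation with n−2 df) is 5'→3' decay; rho < −0.3 is 3'→5'; anything
else is directionless. At least 10 unmasked bases are required for a call —
below that no P-value can reach the 0.0005 threshold meaningfully. The
earlier time points' rho values are reported descriptively; classification
uses t10 only.

Segmental decay: for operons with ≥ 2 fitted members,
(max − min)/mean of the member half-lives; > 0.5 and > 1.0 (strict) define
the two spread classes.

## Covariate analysis

All tests run on log half-life and log expression, with numeric covariates
scaled by their standard deviation. The engine is a *cyclic* ANOVA: for
each factor in turn, the response is regressed on all other factors
(categorical factors as indicator columns; aliased factors dropped with a
warning) and the factor of interest is tested against the residuals —
numeric factors by a Pearson correlation test (the reported coefficient is
thus a partial correlation), categorical ones by a one-way F-test.
Analyses of this kind are sometimes labelled "PCA" in the transcriptomics
literature, but no eigen-decomposition is involved here: the residualized
per-factor procedure is what is implemented. Post-hoc class contrasts use Welch's unequal-variance t-test
of log half-lives (level vs all other fitted genes), with fixed α = 0.005
and a strict minimum of more than 25 members per level — the multiple-
testing convention adopted here instead of FDR machinery. Reported class
means are arithmetic means of raw minutes; capped genes enter at 15 by
default, with an exclusion switch.

Sequence-attribute factors: the RBS window is the first five of the last
six RBS bases (the stretch that pairs with the anti-Shine-Dalgarno 3' tail
of 16S rRNA); the window's 2nd and last base and per-position canonical
pairing flags become categorical levels. Stem-loop candidates (positions
with externally supplied folding energies — folding itself is out of scope)
are counted per gene in 36 groups: four nested energy bins (< −5, −7, −9,
−11 kcal/mol; a −12 site counts in all four, per the "lower than" phrasing;
a disjoint-bin mode is available), three downstream-window lengths (7/9/11
nt) and three downstream G+C counts (0/1/2). Sites are assigned to genes by
position only, as the coverage data are unstranded. The G+C bias
adjustment Exp_adj = Exp × (G+C% × −0.05 + 2.5) applies only within the
30–40% G+C window (factor 1 at 30%, ½ at 40%) and leaves other genes
untouched.

## The synthetic-data generator

The generator emulates a transcriptional-arrest experiment on a
*B. cereus*-like genome. There is no mechanistic generative model for real
decay data, so all distributions are stand-ins, calibrated once to summary
statistics typical of exponentially growing *B. cereus*-group cultures and
configurable throughout:

- **Layout**: operons of 1–12 genes (one-third monocistronic, mean ≈ 3.3
  genes) on alternating strands, gene lengths log-normal (median 800 bp),
  5'/3' UTRs log-normal (medians 75/31 nt), intra-operon gaps 20–80 bp,
  intergenic gaps 150–400 bp. Default 300 operons ≈ 1,000 genes on a
  ~1.4 Mb replicon.
- **Decay truth**: half-lives log-normal, median 2.4 min, σ = 0.55
  (interquartile range ≈ 1.7–3.6 min), truncated to [0.3, 40] min so both
  the 50-RPK floor and the 15-min cap are exercised. Expression log-normal
  on the RPK scale, median 800 (≈ 41 reads/bp of t0 coverage at 52-nt
  reads; mean coverage ≈ 68×). A Gaussian copula couples log half-life to
  log expression (r = 0.33) and to the gene's realized G+C fraction
  (r = 0.27), the planted signals the covariate stage recovers. Direction
  classes are drawn 0.22/0.22/0.56 (5'→3' / 3'→5' / none); gradient genes
  vary their per-base half-life linearly along the transcript by
  ±gradient_strength/2 (default 0.8, i.e. ±40%). 30% of multi-gene operons
  are segmental: one internal gene block is forced ≥ 2.5-fold shorter-lived
  than the rest of its operon.
- **Coverage**: expected coverage c₀·2^(−t/t½(x)) per base with
  c₀ = RPK × read_length/1000, UTR and intra-operon gap bases extending the
  adjacent gene edges so operons are contiguous; optional per-base Poisson
  noise. Library depth uses a fixed-read-budget model by default
  (`depth_mode="fixed_total"`): each sample is rescaled to the t0 expected
  total read count — bulk decay does not appear as a coverage drop, which
  is precisely why anchor normalization is needed — with configurable
  lane-to-lane distortion factors on top (defaults 0.8/1.25/0.8). The
  `explicit` mode applies the factors directly to decayed coverage and is
  what the normalization-exactness tests use with arbitrary distortions.
- **qPCR anchors**: target Ct rises by t/t½ cycles (perfect doubling;
  efficiency calibration is out of scope), the 16S reference Ct is constant,
  and Gaussian Ct noise (default sd 0.1 cycles) is added. The written
  dataset draws five anchors from well-expressed genes with half-life
  ≥ 2 min — anchors must remain measurable across the whole chase.

Everything is deterministic given the seed. What the generator does *not*
emulate: sequencing-error and fragment-length biases, strand-specific or
antisense transcription, multi-mapping reads, operon read-through
variability, or biological replicate-to-replicate decay differences.
Passing recovery tests therefore show the estimators are correct under
Poisson sampling and unknown depth distortions — not that real libraries
meet those assumptions.

## Recovery behaviour and problem sizes

On the default genome (two replicates, Poisson noise) the pipeline recovers
planted half-lives with a median relative error of ≈ 3% among retained
genes, classifies planted gradients with ≥ 90% accuracy where the
noise-attenuated profile correlation (computed analytically from the truth
as sd(signal)/√(var(signal) + mean Poisson log-ratio noise variance))
reaches 0.5, and makes false direction calls on flat genes at well under
2% (the 0.0005 P-threshold is the binding control). Mean rho over ORFs
*classified* 5'→3' grows over the chase (t2.5 → t5 → t10) as the positional
signal accumulates; over all planted gradient genes, including
sub-threshold ones, the last step can invert slightly because short-lived
genes lose unmasked bases at t10.

Calibration checks run at sizes chosen for statistical power at desk
scale: type-I error of the cyclic ANOVA over 500 null simulations of 200
genes; post-hoc null rejection over 500 simulations of 400 genes;
covariate sign recovery over 100 generator draws of ≈ 330 genes (the sign
of a 0.27 partial correlation is not reliably identified much below ~150
observations, so smaller draws would measure sampling noise rather than
pipeline correctness).

## Numerical and degenerate-input choices

- Thresholds follow their stated strictness everywhere: mean coverage
  "> 5", gaps "≤ 5", expression "< 50 excludes", R² "< 0.8 excludes",
  spread "> 50%/100%", class size "> 25".
- A log-linear fit with zero residual variance (e.g. a perfectly constant
  series) has R² defined as 1: the model fits exactly; the k ≤ 0 branch
  then caps it.
- Spearman P-values use the t-distribution approximation (n − 2 df); exact
  enumeration is intractable at ORF length and the approximation is
  standard at n ≥ 10.
- All-tied rank inputs have undefined rho; such ORFs are excluded rather
  than assigned 0.
- Circular replicons are not handled; coordinates are treated as linear
  (rotate coordinates externally for an origin-spanning TU).
- Internal coordinates are 0-based half-open; GFF3 I/O is 1-based
  inclusive, bedGraph 0-based half-open; TU identifiers print 1-based
  inclusive coordinates (`TU_<start>-<end>_<F|R>`, `_U` when no annotated
  gene assigns an orientation).
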