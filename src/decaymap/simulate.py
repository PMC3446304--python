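"""Synthetic rifampicin time-course data with planted decay parameters.

The generator emulates the structure of a bacterial transcriptional-arrest
experiment: operons of 1-12 genes laid out on alternating strands, per-gene
steady-state abundance (RPK scale), first-order exponential decay with
half-lives on a log-normal scale (median 2.4 min), within-ORF positional
decay gradients (5'->3', 3'->5' or none), segmental operons in which an
internal block of genes decays at least two-fold faster, per-time-point
library-depth distortions, Poisson-distributed per-base coverage, and noisy
qPCR anchor measurements referenced to a stable 16S signal.

All distributional choices are configurable; there is no mechanistic
generative model for real decay data, so the defaults are stand-ins
calibrated to summary statistics typical of exponentially growing
B. cereus-group cultures (median half-life, half-life IQR, expression
scale, direction proportions, mean G+C).

Every function is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_bedgraph, write_fasta, write_gff3, write_tsv
from .models import (
    FIVE_TO_THREE,
    NO_DIRECTION,
    THREE_TO_FIVE,
    CoverageTrack,
    GeneRecord,
)

LN2 = math.log(2.0)

_DEFAULT_OPERON_SIZES = {
    1: 0.33, 2: 0.15, 3: 0.13, 4: 0.11, 5: 0.09, 6: 0.07,
    7: 0.05, 8: 0.03, 9: 0.02, 10: 0.01, 11: 0.005, 12: 0.005,
}

_COG_LETTERS = "CDEFGHIJKLMNOPQTUV"


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    half_life_median / half_life_sigma: log-normal scale of true half-lives,
    in minutes (median 2.4, sigma 0.55 reproduces an IQR of roughly
    1.7-3.6 min). Half-lives are truncated to [0.3, 40] min so that both
    the low-expression exclusion floor and the 15-min reporting cap are
    exercised downstream.

    expression_median / expression_sigma: log-normal per-gene abundance on
    the RPK scale. The default median of 800 RPK corresponds to ~41 reads/bp
    of t0 coverage at 52-nt reads, i.e. a deeply covered library whose mean
    coverage exceeds 50x.

    expr_coupling / gc_coupling: Pearson correlations, on the log scale,
    between half-life and expression resp. G+C fraction (Gaussian copula).

    depth_factors / depth_mode: per-time-point library-size distortions the
    normalization stage must undo. With ``depth_mode='fixed_total'`` (the
    default) every sample is first rescaled to the t0 total read count —
    libraries are sequenced to a fixed read budget, so the bulk decay of the
    RNA pool does not show up as a drop in coverage; ``depth_factors`` then
    act as additional lane-to-lane distortions on top. With
    ``depth_mode='explicit'`` the factors are applied as-is and coverage
    carries the full bulk decay.
    """

    n_replicons: int = 1
    replicon_length: int | None = None  # auto-sized when None
    n_operons: int = 300
    genes_per_operon: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_OPERON_SIZES))
    gene_length_median: float = 800.0
    gene_length_sigma: float = 0.35
    gene_length_min: int = 300
    half_life_median: float = 2.4
    half_life_sigma: float = 0.55
    half_life_bounds: tuple[float, float] = (0.3, 40.0)
    expression_median: float = 800.0
    expression_sigma: float = 1.0
    expr_coupling: float = 0.33
    gc_coupling: float = 0.27
    gc_mean: float = 0.355
    gc_sd: float = 0.03
    direction_mix: dict[str, float] = field(default_factory=lambda: {
        FIVE_TO_THREE: 0.22, THREE_TO_FIVE: 0.22, NO_DIRECTION: 0.56})
    gradient_strength: float = 0.8
    segmental_fraction: float = 0.3
    depth_factors: dict[float, float] = field(default_factory=lambda: {
        0.0: 1.0, 2.5: 0.8, 5.0: 1.25, 10.0: 0.8})
    depth_mode: str = "fixed_total"  # or 'explicit'
    timepoints: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0)
    n_replicates: int = 2
    read_length: int = 52
    noise: str = "poisson"  # 'none' or 'poisson'
    utr5_median: float = 75.0
    utr3_median: float = 31.0
    utr_sigma: float = 0.4
    intra_operon_gap: tuple[int, int] = (20, 80)
    intergenic_gap: tuple[int, int] = (150, 400)
    strain: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (("genes_per_operon", self.genes_per_operon),
                            ("direction_mix", self.direction_mix)):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} proportions must sum to 1 (got {total})")
        if any(f <= 0 for f in self.depth_factors.values()):
            raise ValueError("depth_factors must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.expr_coupling ** 2 + self.gc_coupling ** 2 > 1.0:
            raise ValueError("expr_coupling^2 + gc_coupling^2 must be <= 1")
        missing = [t for t in self.timepoints if t not in self.depth_factors]
        if missing:
            raise ValueError(f"no depth factor for time points {missing}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DecayParams:
    """Generative truth: per-gene half-life, abundance and gradient class.

    ``profile(gene)`` exposes the per-base half-life across an ORF; for
    direction 'none' it is constant, otherwise it varies linearly along the
    direction of transcription by ``gradient_strength``.
    """

    half_life: dict[str, float]
    expression: dict[str, float]  # RPK scale
    direction: dict[str, str]
    gradient_strength: float
    segmental_operons: set[str]

    def profile(self, gene: GeneRecord) -> np.ndarray:
        """Per-base half-life over the ORF, in genomic coordinate order."""
        t = self.half_life[gene.gene_id]
        n = gene.length
        if self.direction[gene.gene_id] == NO_DIRECTION or self.gradient_strength == 0:
            return np.full(n, t)
        frac = (np.arange(n) + 0.5) / n  # position along genomic coords
        if gene.strand == "-":
            frac = 1.0 - frac  # transcription runs right to left
        slope = self.gradient_strength
        if self.direction[gene.gene_id] == THREE_TO_FIVE:
            slope = -slope
        prof = t * (1.0 + slope * (frac - 0.5))
        return np.maximum(prof, 0.05)

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "true_half_life_min": self.half_life[g],
             "direction": self.direction[g], "true_expression": self.expression[g]}
            for g in self.half_life
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome construction


def _draw_categorical(rng: np.random.Generator, probs: dict, size: int):
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def make_genome(config: SimConfig,
                ) -> tuple[list[GeneRecord], dict[str, str], dict[str, tuple[int, int]]]:
    """Lay out non-overlapping operons on alternating strands.

    Returns (genes, sequences, operon_spans) where operon_spans maps
    operon_id to the transcript interval (including UTRs) on its replicon.
    Raises ValueError when a fixed replicon_length cannot hold the request.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    sequences: dict[str, str] = {}
    operon_spans: dict[str, tuple[int, int]] = {}

    per_replicon = [config.n_operons // config.n_replicons] * config.n_replicons
    per_replicon[0] += config.n_operons - sum(per_replicon)

    op_counter = 0
    for r in range(config.n_replicons):
        replicon = f"replicon_{r + 1}"
        n_ops = per_replicon[r]
        sizes = _draw_categorical(rng, config.genes_per_operon, n_ops)
        cursor = int(rng.integers(*config.intergenic_gap))
        gc_segments: list[tuple[int, int, float]] = []  # (start, end, gc) per gene
        for i in range(n_ops):
            op_counter += 1
            operon_id = f"op_{op_counter:04d}"
            strand = "+" if op_counter % 2 else "-"
            utr5 = int(rng.lognormal(math.log(config.utr5_median), config.utr_sigma))
            utr3 = int(rng.lognormal(math.log(config.utr3_median), config.utr_sigma))
            op_start = cursor
            pos = cursor + (utr5 if strand == "+" else utr3)
            members: list[GeneRecord] = []
            for j in range(sizes[i]):
                if j > 0:
                    pos += int(rng.integers(*config.intra_operon_gap))
                length = max(config.gene_length_min, int(rng.lognormal(
                    math.log(config.gene_length_median), config.gene_length_sigma)))
                gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.25, 0.50))
                gene = GeneRecord(
                    gene_id=f"gene_{op_counter:04d}_{j + 1}",
                    replicon=replicon, start=pos, end=pos + length, strand=strand,
                    gc_fraction=gc,
                    cog_class=str(rng.choice(list(_COG_LETTERS))),
                    rbs_sequence="".join(rng.choice(list("ACGT"), size=6)),
                    operon_id=operon_id,
                )
                members.append(gene)
                gc_segments.append((pos, pos + length, gc))
                pos += length
            pos += utr3 if strand == "+" else utr5
            if strand == "-":
                # gene order within a reverse operon: first transcribed gene is rightmost
                for idx, g in enumerate(reversed(members)):
                    g.gene_id = f"gene_{op_counter:04d}_{idx + 1}"
            genes.extend(members)
            operon_spans[operon_id] = (op_start, pos)
            cursor = pos + int(rng.integers(*config.intergenic_gap))
        total_span = cursor
        if config.replicon_length is not None:
            if config.replicon_length < total_span:
                raise ValueError(
                    f"replicon_length {config.replicon_length} too short for "
                    f"{n_ops} operons (need >= {total_span})")
            length = config.replicon_length
        else:
            length = total_span
        sequences[replicon] = _draw_sequence(rng, length, gc_segments)
    return genes, sequences, operon_spans


def _draw_sequence(rng: np.random.Generator, length: int,
                   gc_segments: list[tuple[int, int, float]],
                   background_gc: float = 0.32) -> str:
    gc = np.full(length, background_gc)
    for s, e, frac in gc_segments:
        gc[s:e] = frac
    u = rng.random(length)
    v = rng.random(length)
    bases = np.where(u < gc, np.where(v < 0.5, "G", "C"), np.where(v < 0.5, "A", "T"))
    return "".join(bases)


# ---------------------------------------------------------------------------
# decay parameters


def assign_decay_params(genes: list[GeneRecord], config: SimConfig) -> DecayParams:
    """Draw per-gene half-lives, abundances and gradient classes.

    log half-life is coupled to log expression (``expr_coupling``) and to the
    realized G+C fraction (``gc_coupling``) through a Gaussian copula, so the
    covariate stage has a known signal to recover. Segmental operons get one
    internal block of genes with a >= 2-fold shorter half-life.
    """
    if not genes:
        raise ValueError("annotation is empty")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = len(genes)

    z_expr = rng.standard_normal(n)
    z_gc = np.array([
        (g.gc_fraction - config.gc_mean) / config.gc_sd if np.isfinite(g.gc_fraction)
        else 0.0
        for g in genes
    ])
    resid = math.sqrt(max(0.0, 1 - config.expr_coupling ** 2 - config.gc_coupling ** 2))
    z_hl = (config.expr_coupling * z_expr + config.gc_coupling * z_gc
            + resid * rng.standard_normal(n))

    expression = np.exp(math.log(config.expression_median)
                        + config.expression_sigma * z_expr)
    half_life = np.exp(math.log(config.half_life_median)
                       + config.half_life_sigma * z_hl)
    half_life = np.clip(half_life, *config.half_life_bounds)

    direction = _draw_categorical(rng, config.direction_mix, n)

    hl_map = {g.gene_id: float(half_life[i]) for i, g in enumerate(genes)}
    expr_map = {g.gene_id: float(expression[i]) for i, g in enumerate(genes)}
    dir_map = {g.gene_id: direction[i] for i, g in enumerate(genes)}

    # segmental operons: one contiguous internal block decays >= 2-fold faster
    by_operon: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.operon_id is not None:
            by_operon.setdefault(g.operon_id, []).append(g)
    multi = sorted(op for op, members in by_operon.items() if len(members) >= 2)
    n_seg = int(round(config.segmental_fraction * len(multi)))
    chosen = sorted(rng.choice(multi, size=n_seg, replace=False)) if n_seg else []
    segmental = set(map(str, chosen))
    lo = config.half_life_bounds[0]
    for op in sorted(segmental):
        members = sorted(by_operon[op], key=lambda g: g.start)
        block_len = int(rng.integers(1, len(members)))
        block_start = int(rng.integers(0, len(members) - block_len + 1))
        block = members[block_start:block_start + block_len]
        rest_min = min(hl_map[g.gene_id] for g in members if g not in block)
        for g in block:
            # >= 2.5-fold shorter than every non-block member
            hl_map[g.gene_id] = max(lo, min(hl_map[g.gene_id], rest_min) * 0.4)

    return DecayParams(half_life=hl_map, expression=expr_map, direction=dir_map,
                       gradient_strength=config.gradient_strength,
                       segmental_operons=set(map(str, segmental)))


# ---------------------------------------------------------------------------
# coverage simulation


def _base_coverage(genes: list[GeneRecord], params: DecayParams,
                   config: SimConfig, replicon: str, length: int,
                   time_min: float,
                   operon_spans: dict[str, tuple[int, int]] | None = None,
                   ) -> np.ndarray:
    """Decayed per-base coverage before any library-depth scaling.

    Base x of gene g decays as c0(g) * 2^(-t / t_half(g, x)), with c0
    converting RPK-scale abundance to reads/bp (c0 = RPK * read_length /
    1000). UTR and intra-operon gap bases extend the adjacent gene's edge
    value so each operon is one contiguous covered stretch; bases outside
    operons are zero.
    """
    cov = np.zeros(length)
    by_operon: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.replicon != replicon:
            continue
        c0 = params.expression[g.gene_id] * config.read_length / 1000.0
        prof = params.profile(g)
        cov[g.start:g.end] = c0 * np.power(2.0, -time_min / prof)
        by_operon.setdefault(g.operon_id or g.gene_id, []).append(g)
    if operon_spans:
        for op, members in by_operon.items():
            if op not in operon_spans:
                continue
            span_start, span_end = operon_spans[op]
            members = sorted(members, key=lambda g: g.start)
            # 5'/3' UTRs extend the terminal genes' edge values
            cov[span_start:members[0].start] = cov[members[0].start]
            cov[members[-1].end:span_end] = cov[members[-1].end - 1]
            # intra-operon gaps interpolate between flanking gene edges
            for a, b in zip(members, members[1:]):
                gap = b.start - a.end
                if gap > 0:
                    cov[a.end:b.start] = np.linspace(
                        cov[a.end - 1], cov[b.start], gap + 2)[1:-1]
    return cov


def effective_depth(genes: list[GeneRecord], params: DecayParams,
                    config: SimConfig, replicon: str, length: int,
                    time_min: float,
                    operon_spans: dict[str, tuple[int, int]] | None = None,
                    ) -> float:
    """Total multiplicative depth distortion applied to one sample.

    In 'fixed_total' mode the sample is rescaled so its expected total read
    count matches t0 (fixed sequencing budget) and the configured factor is
    an extra lane distortion; in 'explicit' mode the configured factor is
    applied directly.
    """
    factor = config.depth_factors[time_min]
    if config.depth_mode == "explicit" or time_min == 0.0:
        return factor
    if config.depth_mode != "fixed_total":
        raise ValueError(f"unknown depth_mode {config.depth_mode!r}")
    total_0 = _base_coverage(genes, params, config, replicon, length, 0.0,
                             operon_spans).sum()
    total_t = _base_coverage(genes, params, config, replicon, length, time_min,
                             operon_spans).sum()
    if total_t <= 0:
        return factor
    return factor * total_0 / total_t


def expected_coverage(genes: list[GeneRecord], params: DecayParams,
                      config: SimConfig, replicon: str, length: int,
                      time_min: float,
                      operon_spans: dict[str, tuple[int, int]] | None = None,
                      ) -> np.ndarray:
    """Noise-free expected per-base coverage at one time point."""
    cov = _base_coverage(genes, params, config, replicon, length, time_min,
                         operon_spans)
    return cov * effective_depth(genes, params, config, replicon, length,
                                 time_min, operon_spans)


def predicted_profile_correlation(gene: GeneRecord, params: DecayParams,
                                  config: SimConfig,
                                  depth: dict[float, float],
                                  time_min: float = 10.0) -> float:
    """Noise-attenuated correlation a planted gradient is expected to yield.

    The per-base log2 decay ratio has signal s(x) = -t / t_half(g, x) and
    approximately independent Poisson sampling noise of variance
    (1/ln2)^2 (1/lambda_t(x) + 1/lambda_0(x)); the expected Pearson
    correlation with position is sd(s) / sqrt(var(s) + mean noise var),
    signed by the gradient direction. Used to decide which planted genes
    carry a recoverable directional signal. ``depth`` maps each time point
    to its effective depth distortion.
    """
    prof = params.profile(gene)
    c0 = params.expression[gene.gene_id] * config.read_length / 1000.0
    lam0 = c0 * depth.get(0.0, 1.0)
    lam_t = c0 * np.power(2.0, -time_min / prof) * depth[time_min]
    signal = -time_min / prof
    var_s = float(np.var(signal))
    noise = float(np.mean((1.0 / LN2) ** 2 * (1.0 / np.maximum(lam_t, 1e-9)
                                              + 1.0 / max(lam0, 1e-9))))
    if var_s == 0:
        return 0.0
    r = math.sqrt(var_s / (var_s + noise))
    if params.direction[gene.gene_id] == THREE_TO_FIVE:
        r = -r
    elif params.direction[gene.gene_id] != FIVE_TO_THREE:
        r = 0.0
    return r


def simulate_coverage(genes: list[GeneRecord], params: DecayParams,
                      config: SimConfig,
                      sequences: dict[str, str] | None = None,
                      operon_spans: dict[str, tuple[int, int]] | None = None,
                      replicon_lengths: dict[str, int] | None = None,
                      ) -> dict[tuple[str, float], list[CoverageTrack]]:
    """Simulate one CoverageTrack per (replicate, time point, replicon).

    Returns a mapping (replicate, time_min) -> list of tracks (one per
    replicon). With ``noise='poisson'`` each base is drawn independently from
    a Poisson law with the expected mean; with ``noise='none'`` the expected
    values are returned as-is. Deterministic given the config seed.
    """
    config.validate()
    if replicon_lengths is None:
        if sequences is None:
            raise ValueError("need sequences or replicon_lengths")
        replicon_lengths = {name: len(seq) for name, seq in sequences.items()}
    rng = np.random.default_rng(config.seed + 2)
    out: dict[tuple[str, float], list[CoverageTrack]] = {}
    for replicon, length in replicon_lengths.items():
        for t in config.timepoints:
            mean = expected_coverage(genes, params, config, replicon, length, t,
                                     operon_spans)
            for rep in range(1, config.n_replicates + 1):
                if config.noise == "poisson":
                    values = rng.poisson(mean).astype(float)
                else:
                    values = mean.copy()
                track = CoverageTrack(replicon=replicon, values=values,
                                      strain=config.strain, replicate=str(rep),
                                      time_min=t)
                out.setdefault((str(rep), t), []).append(track)
    return out


# ---------------------------------------------------------------------------
# qPCR anchors


def simulate_qpcr(params: DecayParams, anchor_ids: list[str],
                  noise_sd_ct: float = 0.1, config: SimConfig | None = None,
                  timepoints: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0),
                  n_replicates: int = 3, seed: int | None = None,
                  ) -> pd.DataFrame:
    """Simulate a ΔΔCt anchor table referenced to a stable 16S signal.

    Target Ct rises by t / t_half cycles over the chase (perfect doubling per
    cycle); the 16S reference Ct is constant over the time course, emulating
    a reference RNA that is not detectably degraded within the 10-minute
    window. Gaussian noise of sd ``noise_sd_ct`` cycles is added to every
    measured Ct.
    """
    unknown = [a for a in anchor_ids if a not in params.half_life]
    if unknown:
        raise KeyError(f"unknown anchor ids: {unknown}")
    if not anchor_ids:
        raise ValueError("need at least one anchor gene")
    if config is not None:
        timepoints = config.timepoints
    if seed is None:
        seed = (config.seed + 3) if config is not None else 0
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id in anchor_ids:
        t_half = params.half_life[gene_id]
        # baseline Ct from abundance: more template -> fewer cycles
        ct0 = 30.0 - math.log2(max(params.expression[gene_id], 1e-9))
        for rep in range(1, n_replicates + 1):
            for t in timepoints:
                ct_target = ct0 + t / t_half + rng.normal(0.0, noise_sd_ct)
                ct_ref = 12.0 + rng.normal(0.0, noise_sd_ct)
                rows.append({"gene_id": gene_id, "replicate": rep, "time_min": t,
                             "ct_target": ct_target, "ct_reference": ct_ref})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(outdir: str | Path, config: SimConfig,
                  n_anchors: int = 5, anchor_noise_sd_ct: float = 0.1) -> dict:
    """Generate a complete synthetic dataset on disk.

    Writes GFF3 annotation, FASTA replicons, one bedGraph per (replicate,
    time point), a truth table, and an anchor Ct table. Anchors are drawn
    from the most abundant genes (mirroring qPCR's need for well-expressed
    targets). Returns a manifest dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, sequences, operon_spans = make_genome(config)
    params = assign_decay_params(genes, config)
    tracks = simulate_coverage(genes, params, config, sequences=sequences,
                               operon_spans=operon_spans)

    rng = np.random.default_rng(config.seed + 4)
    # anchors must stay measurable across the whole chase: well expressed,
    # and not so short-lived that they vanish from late samples
    measurable = [g for g in params.expression if params.half_life[g] >= 2.0]
    ranked = sorted(measurable or params.expression,
                    key=params.expression.get, reverse=True)
    pool = ranked[:max(n_anchors * 4, n_anchors)]
    anchor_ids = sorted(rng.choice(pool, size=min(n_anchors, len(pool)),
                                   replace=False))
    qpcr = simulate_qpcr(params, list(anchor_ids), noise_sd_ct=anchor_noise_sd_ct,
                         config=config)

    manifest: dict = {"outdir": str(outdir), "files": {}}
    gff = outdir / "annotation.gff3"
    write_gff3(genes, gff)
    fasta = outdir / "genome.fasta"
    write_fasta(sequences, fasta)
    manifest["files"]["annotation"] = str(gff)
    manifest["files"]["fasta"] = str(fasta)
    manifest["files"]["coverage"] = []
    for (rep, t), track_list in sorted(tracks.items()):
        for track in track_list:
            path = outdir / f"{track.sample_name}.bedGraph"
            write_bedgraph(track, path)
            manifest["files"]["coverage"].append(str(path))
    truth = outdir / "truth.tsv"
    write_tsv(params.truth_table(), truth, [f"seed: {config.seed}"])
    anchors = outdir / "anchors_ct.tsv"
    write_tsv(qpcr, anchors, [f"seed: {config.seed}"])
    ops = pd.DataFrame([
        {"operon_id": op, "start": s, "end": e,
         "segmental": op in params.segmental_operons}
        for op, (s, e) in operon_spans.items()])
    ops_path = outdir / "operons.tsv"
    write_tsv(ops, ops_path)
    manifest["files"]["truth"] = str(truth)
    manifest["files"]["anchors_ct"] = str(anchors)
    manifest["files"]["operons"] = str(ops_path)
    manifest["anchor_ids"] = list(anchor_ids)
    return manifest
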