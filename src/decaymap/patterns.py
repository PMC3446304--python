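"""Per-nucleotide decay profiles, decay directionality and segmental decay.

For every TU whose mean t0 coverage is at least 50 reads/bp, a profile of
log2((coverage_t x f_t) / coverage_t0) is built per post-arrest time point.
Decay direction is then classified per ORF (not per TU, since segmental
operons would mask per-gene behaviour) by the Spearman rank correlation
between the t10 log2 ratio and the distance from the ORF start measured in
the direction of transcription: rho > 0.3 with P < 0.0005 is 5'->3' decay
(faster loss near the 5' end), rho < -0.3 with P < 0.0005 is 3'->5', and
anything else is called 'none'. Earlier time points' rho values are
reported for trend checks only.
"""

from __future__ import annotations

import numpy as np

from .models import (
    FIVE_TO_THREE,
    NO_DIRECTION,
    STATUS_OK,
    THREE_TO_FIVE,
    CoverageTrack,
    DecayProfile,
    DirectionCall,
    GeneRecord,
    HalfLifeRecord,
    SegmentalCall,
    TranscriptionalUnit,
)
from .quantify import NormalizationFactors


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties share average ranks. All-tied input has no defined rank ordering;
    rho is returned as NaN and callers exclude the ORF.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def profile_operon(tracks_by_time: dict[float, CoverageTrack],
                   factors: NormalizationFactors, tu: TranscriptionalUnit,
                   min_t0_mean: float = 50.0) -> DecayProfile | None:
    """log2 decay-ratio profile over one TU, or None below the t0 threshold.

    Bases with zero coverage at t0 or at the later time point are masked
    (NaN): a rank statistic is sensitive to imputed floors, so no
    pseudocount is applied here (plotting uses one separately).
    """
    t0 = tracks_by_time[0.0]
    cov0 = t0.values[tu.start:tu.end]
    t0_mean = float(cov0.mean())
    if t0_mean < min_t0_mean:
        return None
    ratios: dict[float, np.ndarray] = {}
    for t, track in tracks_by_time.items():
        if t == 0.0:
            continue
        f = factors.factors[t]
        cov_t = track.values[tu.start:tu.end] * f
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(cov_t / cov0)
        ratio[(cov0 <= 0) | (cov_t <= 0)] = np.nan
        ratios[t] = ratio
    return DecayProfile(tu_id=tu.tu_id, start=tu.start, end=tu.end,
                        ratios=ratios, t0_mean=t0_mean)


def classify_direction(profile: DecayProfile, orf: GeneRecord,
                       rho_threshold: float = 0.3,
                       p_threshold: float = 0.0005,
                       min_bases: int = 10,
                       classify_at: float = 10.0) -> DirectionCall | None:
    """Classify one ORF's decay direction from its profile.

    x is the distance from the ORF start in the direction of transcription
    (so a minus-strand ORF losing its 5' end faster still yields positive
    rho); y is the log2 ratio at the classification time point (t10).
    Returns None when fewer than ``min_bases`` unmasked bases overlap.
    """
    lo = max(orf.start, profile.start)
    hi = min(orf.end, profile.end)
    if hi <= lo:
        return None
    genomic = np.arange(lo, hi)
    if orf.strand == "+":
        dist = genomic - orf.start
    else:
        dist = (orf.end - 1) - genomic
    rho_by_time: dict[float, float] = {}
    p10 = float("nan")
    n10 = 0
    for t, ratio in sorted(profile.ratios.items()):
        y = ratio[lo - profile.start:hi - profile.start]
        ok = np.isfinite(y)
        if ok.sum() < min_bases:
            rho_by_time[t] = float("nan")
            continue
        rho, p = spearman_rho(dist[ok], y[ok])
        rho_by_time[t] = rho
        if t == classify_at:
            p10 = p
            n10 = int(ok.sum())
    rho10 = rho_by_time.get(classify_at, float("nan"))
    if not np.isfinite(rho10):
        return None
    if rho10 > rho_threshold and p10 < p_threshold:
        direction = FIVE_TO_THREE
    elif rho10 < -rho_threshold and p10 < p_threshold:
        direction = THREE_TO_FIVE
    else:
        direction = NO_DIRECTION
    return DirectionCall(gene_id=orf.gene_id, rho_by_time=rho_by_time,
                         p_value=p10, direction=direction, n_bases=n10)


def segmental_calls(tus: list[TranscriptionalUnit],
                    records: list[HalfLifeRecord]) -> list[SegmentalCall]:
    """Within-operon half-life spread, for operons with >= 2 fitted members.

    relative_spread = (max - min) / mean over the fitted member half-lives;
    classes use strict thresholds (> 0.5, > 1.0).
    """
    by_gene = {r.gene_id: r for r in records if r.status == STATUS_OK}
    calls = []
    for tu in tus:
        values = [by_gene[g].half_life for g in tu.member_gene_ids
                  if g in by_gene]
        if len(values) < 2:
            continue
        calls.append(SegmentalCall(
            tu_id=tu.tu_id, min_half_life=float(min(values)),
            max_half_life=float(max(values)),
            mean_half_life=float(np.mean(values)), n_members=len(values)))
    return calls


def plot_profile(profile: DecayProfile, tracks_by_time: dict[float, CoverageTrack],
                 path: str, factors: NormalizationFactors | None = None,
                 pseudocount: float = 1.0) -> None:
    """Two-panel figure: t0 coverage and per-time log2 decay ratios.

    For drawing only, masked bases are recomputed with a pseudocount so the
    curves are finite; the statistics above never see these values.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(profile.start, profile.end)
    cov0 = tracks_by_time[0.0].values[profile.start:profile.end]
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax0.fill_between(x, cov0, color="0.6")
    ax0.set_ylabel("t0 coverage (reads/bp)")
    ax0.set_title(profile.tu_id)
    colors = {2.5: "tab:red", 5.0: "tab:green", 10.0: "tab:blue"}
    for t, ratio in sorted(profile.ratios.items()):
        drawn = ratio.copy()
        nan = ~np.isfinite(drawn)
        if nan.any():
            f = factors.factors[t] if factors is not None else 1.0
            cov_t = tracks_by_time[t].values[profile.start:profile.end] * f
            drawn[nan] = np.log2((cov_t[nan] + pseudocount)
                                 / (cov0[nan] + pseudocount))
        ax1.plot(x, drawn, lw=0.7, color=colors.get(t), label=f"t{t:g}")
    ax1.axhline(0, color="k", lw=0.5)
    ax1.set_ylabel("log2(cov_t / cov_t0)")
    ax1.set_xlabel("genome position (bp)")
    ax1.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
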