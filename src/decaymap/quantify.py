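"""Expression quantification and anchor-based normalization.

RPK (reads per kilobase of CDS) is the working expression unit; RPKM
additionally scales by the sample's total mapped reads. Samples from
different time points of the chase are not directly comparable (library
depth and residual-rRNA effects differ), so each post-arrest time point is
rescaled by a factor derived from anchor genes whose decay was measured
independently by 16S-referenced ΔΔCt RT-qPCR: the factor is the geometric
mean, over anchors, of (qPCR-expected RPK) / (observed RPK). t0 is the
reference and is never rescaled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import CoverageTrack, GeneRecord

LN2 = math.log(2.0)


def fragment_length(gap_nt: float, *read_lengths: float) -> float:
    """Paired-end fragment length: inner gap plus the two read lengths.

    A pair of 36-nt reads with a 174-nt inner gap spans a 246-nt fragment.
    """
    return gap_nt + sum(read_lengths)


def gene_rpk(coverage: CoverageTrack, gene: GeneRecord,
             read_length: int = 52) -> float:
    """Reads per kilobase of CDS, with reads estimated from base coverage.

    reads = (sum of per-base coverage over the CDS) / read_length;
    RPK = reads x 1000 / CDS length (bp).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if gene.start < 0 or gene.end > len(coverage):
        raise ValueError(f"{gene.gene_id} outside track bounds")
    reads = float(coverage.values[gene.start:gene.end].sum()) / read_length
    return reads * 1000.0 / gene.length


def rpkm(rpk: float, total_mapped_reads: float) -> float:
    """RPK per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return rpk * 1e6 / total_mapped_reads


def total_reads(coverage: CoverageTrack, read_length: int = 52) -> float:
    return float(coverage.values.sum()) / read_length


def expression_table(tracks: dict[tuple[str, float], list[CoverageTrack]],
                     genes: list[GeneRecord],
                     read_length: int = 52) -> pd.DataFrame:
    """Tidy per-(gene, replicate, time) raw RPK table from coverage tracks."""
    rows = []
    for (rep, t), track_list in sorted(tracks.items()):
        by_replicon = {tr.replicon: tr for tr in track_list}
        for g in genes:
            track = by_replicon.get(g.replicon)
            if track is None:
                continue
            rows.append({"gene_id": g.gene_id, "replicate": rep, "time_min": t,
                         "rpk_raw": gene_rpk(track, g, read_length)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR anchors


def qpcr_halflife(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Anchor half-lives from a ΔΔCt table referenced to a stable RNA.

    Expects columns gene_id, time_min, ct_target, ct_reference (replicate
    rows are averaged per time point before fitting). Relative abundance
    R(t) = 2^-(ΔCt_t - ΔCt_0) with ΔCt = ct_target - ct_reference; the
    half-life is ln2 / (-slope) of the least-squares line ln R(t) ~ t.
    A non-decaying series (slope >= 0) yields half_life = inf, to be capped
    by the reporting stage.
    """
    required = {"gene_id", "time_min", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    rows = []
    for gene_id, sub in ct_table.groupby("gene_id"):
        mean = sub.groupby("time_min")[["ct_target", "ct_reference"]].mean()
        if len(mean) < 3 or 0.0 not in mean.index:
            raise ValueError(f"{gene_id}: need >= 3 time points including t0")
        dct = mean["ct_target"] - mean["ct_reference"]
        ddct = dct - dct.loc[0.0]
        ln_r = -ddct.to_numpy() * LN2  # ln R(t) = -ΔΔCt * ln 2
        fit = stats.linregress(mean.index.to_numpy(), ln_r)
        k = -fit.slope
        half_life = LN2 / k if k > 0 else math.inf
        rows.append({"gene_id": gene_id, "half_life_min": half_life,
                     "slope": fit.slope, "r_squared": fit.rvalue ** 2})
    return pd.DataFrame(rows)


@dataclass
class NormalizationFactors:
    """Per-time-point scale factors and their per-anchor components.

    ``factors[t]`` is the geometric mean of ``components[t][anchor]``; raw
    post-arrest RPK values are multiplied by the factor for their time point.
    """

    factors: dict[float, float]
    components: dict[float, dict[str, float]] = field(default_factory=dict)
    excluded_anchors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.factors):
            row = {"time_min": t, "factor": self.factors[t]}
            for anchor, comp in sorted(self.components.get(t, {}).items()):
                row[f"component_{anchor}"] = comp
            rows.append(row)
        return pd.DataFrame(rows)


def anchor_factors(anchor_half_lives: dict[str, float],
                   raw_rpk: pd.DataFrame) -> NormalizationFactors:
    """Per-time-point normalization factors from qPCR-anchored decay curves.

    For anchor g at time t > 0 the qPCR-expected abundance is
    rpk_raw(g, 0) x 2^(-t / t_half(g)); the component factor is
    expected / observed, and the time point's factor is the geometric mean
    of the components. Anchors with zero raw RPK at any time point are
    excluded with a warning; an anchor set that excludes everything is an
    error.

    ``raw_rpk`` is tidy with columns gene_id, time_min, rpk_raw (replicate
    rows, if present, are averaged first).
    """
    if not anchor_half_lives:
        raise ValueError("need at least one anchor")
    sub = raw_rpk[raw_rpk["gene_id"].isin(anchor_half_lives)]
    wide = (sub.groupby(["gene_id", "time_min"])["rpk_raw"].mean()
            .unstack("time_min"))
    missing = set(anchor_half_lives) - set(wide.index)
    if missing:
        raise ValueError(f"no RPK data for anchors: {sorted(missing)}")
    usable = {}
    excluded = []
    for gene_id, row in wide.iterrows():
        if (row <= 0).any() or row.isna().any():
            excluded.append(gene_id)
            warnings.warn(f"anchor {gene_id} has zero/missing RPK; excluded")
        else:
            usable[gene_id] = row
    if not usable:
        raise ValueError("all anchors excluded (zero RPK at some time point)")
    times = [t for t in wide.columns if t > 0]
    factors: dict[float, float] = {}
    components: dict[float, dict[str, float]] = {}
    for t in times:
        comps = {}
        for gene_id, row in usable.items():
            expected = row[0.0] * 2.0 ** (-t / anchor_half_lives[gene_id])
            comps[gene_id] = expected / row[t]
        components[t] = comps
        factors[t] = float(stats.gmean(list(comps.values())))
    return NormalizationFactors(factors=factors, components=components,
                                excluded_anchors=excluded)


def apply_normalization(expression: pd.DataFrame,
                        factors: NormalizationFactors) -> pd.DataFrame:
    """Fill rpk_norm: raw RPK x f_t for t > 0, unchanged at t0."""
    times = set(expression.loc[expression["time_min"] > 0, "time_min"])
    missing = times - set(factors.factors)
    if missing:
        raise ValueError(f"no factor for time points {sorted(missing)}")
    out = expression.copy()
    f = out["time_min"].map(lambda t: factors.factors.get(t, 1.0) if t > 0 else 1.0)
    out["rpk_norm"] = out["rpk_raw"] * f
    return out
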