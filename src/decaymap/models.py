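"""Core record types shared across the pipeline.

Coordinate convention: all in-memory coordinates are 0-based, half-open
``[start, end)``. File I/O converts at the boundary (GFF3 is 1-based
inclusive, bedGraph is 0-based half-open). TU identifiers are printed with
1-based inclusive coordinates (``TU_<start>-<end>_<F|R>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# TU association flags
TSS_INSIDE_GENE = "TSS_inside_gene"
TES_INSIDE_GENE = "TES_inside_gene"
SPLIT_DIVERGENT = "split_divergent"
SPLIT_CONVERGENT = "split_convergent"
FUSED_BY_KMER = "fused_by_kmer"

# decay-direction classes
FIVE_TO_THREE = "five_to_three"
THREE_TO_FIVE = "three_to_five"
NO_DIRECTION = "none"

# half-life record statuses
STATUS_OK = "ok"
STATUS_LOW_RPK = "excluded_low_rpk"
STATUS_POOR_FIT = "excluded_poor_fit"
STATUS_MISSING = "excluded_missing"


@dataclass
class GeneRecord:
    """An annotated CDS.

    ``start``/``end`` are genomic 0-based half-open; ``strand`` is '+' or '-'.
    Optional functional attributes feed the covariate analysis.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    gc_fraction: float = float("nan")
    cog_class: str | None = None
    kegg_pathways: tuple[str, ...] = ()
    rbs_sequence: str | None = None
    repeat_families: tuple[str, ...] = ()
    is_pseudogene: bool = False
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base, non-negative read coverage for one sample on one replicon."""

    replicon: str
    values: np.ndarray
    strain: str = "sim"
    replicate: str = "1"
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def sample_name(self) -> str:
        t = f"{self.time_min:g}".replace(".", "p")
        return f"{self.strain}_{self.replicate}_t{t}"


@dataclass
class TranscriptionalUnit:
    """A called transcript interval with its member genes and flags."""

    replicon: str
    start: int
    end: int
    orientation: str = "unassigned"  # 'F', 'R' or 'unassigned'
    member_gene_ids: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    mean_coverage: float = float("nan")

    @property
    def tu_id(self) -> str:
        suffix = {"F": "F", "R": "R"}.get(self.orientation, "U")
        return f"TU_{self.start + 1}-{self.end}_{suffix}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


@dataclass
class HalfLifeRecord:
    """Per-gene fitted half-life with quality and exclusion status.

    ``half_life`` is None whenever ``status != 'ok'``. Capped records carry
    half_life equal to the cap (15 min by default) with ``capped=True``.
    """

    gene_id: str
    status: str
    half_life: float | None = None
    capped: bool = False
    r_squared: float | None = None
    n_points_used: int = 0


@dataclass
class DecayProfile:
    """Per-base log2(coverage_t x f_t / coverage_t0) over one TU.

    ``ratios`` maps each post-arrest time point to an array of TU length;
    bases with zero coverage at t0 or at t are NaN (masked).
    """

    tu_id: str
    start: int
    end: int
    ratios: dict[float, np.ndarray]
    t0_mean: float


@dataclass
class DirectionCall:
    """Per-ORF decay-direction classification from rank statistics."""

    gene_id: str
    rho_by_time: dict[float, float]
    p_value: float
    direction: str
    n_bases: int


@dataclass
class SegmentalCall:
    """Within-operon half-life spread relative to the operon mean."""

    tu_id: str
    min_half_life: float
    max_half_life: float
    mean_half_life: float
    n_members: int

    @property
    def relative_spread(self) -> float:
        return (self.max_half_life - self.min_half_life) / self.mean_half_life

    @property
    def spread_class(self) -> str:
        s = self.relative_spread
        if s > 1.0:
            return "spread_gt_100"
        if s > 0.5:
            return "spread_gt_50"
        return "uniform"
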