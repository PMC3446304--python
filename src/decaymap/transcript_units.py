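"""Transcriptional-unit and operon calling from pooled per-base coverage.

The rule set: every maximal run of non-zero pooled coverage whose mean is
strictly above 5 reads/bp is a candidate TU; candidates separated by a zero
gap of 5 bp or less are fused; adjacent TUs whose facing ends both fall in
the same non-unique 52-mer region (unmappable by single-end 52-nt reads)
are fused; TUs are then associated with annotated genes, flagged when their
boundaries fall inside a CDS, and split when they cover genes on both
strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    FUSED_BY_KMER,
    SPLIT_CONVERGENT,
    SPLIT_DIVERGENT,
    TES_INSIDE_GENE,
    TSS_INSIDE_GENE,
    CoverageTrack,
    GeneRecord,
    TranscriptionalUnit,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class RawTU:
    """An interval called from coverage, before gene association."""

    start: int
    end: int
    mean_coverage: float
    flags: set[str] = field(default_factory=set)


def pool_coverage(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-base sum of coverage across samples (all on one replicon)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if t.replicon != first.replicon or len(t) != len(first):
            raise ValueError("tracks differ in replicon or length")
    values = np.sum([t.values for t in tracks], axis=0)
    return CoverageTrack(replicon=first.replicon, values=values,
                         strain=first.strain, replicate="pooled", time_min=0.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def call_raw_tus(pooled: CoverageTrack, min_mean: float = 5.0,
                 merge_gap: int = 5) -> list[RawTU]:
    """Call TUs: filter covered stretches by mean, then fuse short gaps.

    A stretch is retained iff its mean coverage is strictly greater than
    ``min_mean``; retained stretches whose intervening zero gap is at most
    ``merge_gap`` bp are fused, and the fused TU's mean is recomputed over
    its full span (gap zeros included).
    """
    v = pooled.values
    kept = [(s, e) for s, e in _runs(v > 0) if v[s:e].mean() > min_mean]
    fused: list[list[int]] = []
    for s, e in kept:
        if fused and s - fused[-1][1] <= merge_gap:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    return [RawTU(s, e, float(v[s:e].mean())) for s, e in fused]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def map_nonunique_kmers(sequence: str, k: int = 52) -> list[tuple[int, int]]:
    """Maximal runs of positions covered only by non-unique k-mers.

    A genome position is flagged iff every k-mer window covering it occurs
    more than once in the genome, counting matches on either strand
    (reverse-complement occurrences included). Reads of length k cannot be
    placed unambiguously anywhere inside such a run.
    """
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence shorter than k ({n} < {k})")
    sequence = sequence.upper()
    counts: dict[str, int] = {}
    canon: list[str] = []
    for i in range(n - k + 1):
        w = sequence[i:i + k]
        c = min(w, _revcomp(w))
        canon.append(c)
        counts[c] = counts.get(c, 0) + 1
    dup = np.array([counts[c] > 1 for c in canon], dtype=np.int64)
    # position p is flagged iff all windows starting in
    # [max(0, p-k+1), min(p, n-k)] are duplicated
    csum = np.concatenate([[0], np.cumsum(dup)])
    p = np.arange(n)
    lo = np.maximum(0, p - k + 1)
    hi = np.minimum(p, n - k)
    n_windows = hi - lo + 1
    n_dup = csum[hi + 1] - csum[lo]
    flagged = n_dup == n_windows
    return _runs(flagged)


def fuse_by_kmer(tus: list[RawTU],
                 flagged_intervals: list[tuple[int, int]]) -> list[RawTU]:
    """Fuse adjacent TUs whose facing ends lie in one unmappable region.

    ``flagged_intervals`` are first merged across direct abutments; a TU pair
    is fused when the last base of the left TU and the first base of the
    right TU fall inside the same merged region. Applied iteratively until
    no further fusion occurs. Fused TUs carry the ``fused_by_kmer`` flag;
    their mean is a span-length-weighted combination of the parts (gap bases
    have unknown coverage and are excluded).
    """
    merged: list[list[int]] = []
    for s, e in sorted(flagged_intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    def region_of(pos: int) -> int | None:
        for i, (s, e) in enumerate(merged):
            if s <= pos < e:
                return i
        return None

    tus = sorted((RawTU(t.start, t.end, t.mean_coverage, set(t.flags))
                  for t in tus), key=lambda t: t.start)
    changed = True
    while changed:
        changed = False
        out: list[RawTU] = []
        for tu in tus:
            if out:
                prev = out[-1]
                ra = region_of(prev.end - 1)
                rb = region_of(tu.start)
                if ra is not None and ra == rb:
                    la, lb = prev.end - prev.start, tu.end - tu.start
                    mean = (prev.mean_coverage * la + tu.mean_coverage * lb) / (la + lb)
                    out[-1] = RawTU(prev.start, tu.end, mean,
                                    prev.flags | tu.flags | {FUSED_BY_KMER})
                    changed = True
                    continue
            out.append(tu)
        tus = out
    return tus


# ---------------------------------------------------------------------------
# gene association


def _strand_blocks(members: list[GeneRecord]) -> list[list[GeneRecord]]:
    blocks: list[list[GeneRecord]] = []
    for g in sorted(members, key=lambda g: g.start):
        if blocks and blocks[-1][0].strand == g.strand:
            blocks[-1].append(g)
        else:
            blocks.append([g])
    return blocks


def _boundary_flags(tu: TranscriptionalUnit, members: list[GeneRecord]) -> None:
    """Flag TUs whose 5'/3' boundary falls inside a member CDS."""
    lo = min(g.start for g in members)
    hi = max(g.end for g in members)
    if tu.orientation == "F":
        if tu.start > lo:
            tu.flags.add(TSS_INSIDE_GENE)
        if tu.end < hi:
            tu.flags.add(TES_INSIDE_GENE)
    else:  # reverse: 5' end of the transcript is the right edge
        if tu.end < hi:
            tu.flags.add(TSS_INSIDE_GENE)
        if tu.start > lo:
            tu.flags.add(TES_INSIDE_GENE)


def associate_genes(tus: list[RawTU], genes: list[GeneRecord],
                    pooled: CoverageTrack) -> list[TranscriptionalUnit]:
    """Associate raw TUs with annotated genes, splitting mixed-strand TUs.

    Rules: a TU whose member genes share one strand becomes an oriented
    transcribed region; boundaries inside a member CDS raise
    TSS_inside_gene / TES_inside_gene; a TU covering genes on both strands
    is split at each strand junction — at convergent junctions (facing 3'
    ends) each fragment's TES is set to its block's annotated gene stop, at
    divergent junctions (facing 5' ends) each fragment's TSS is set to the
    annotated gene start. TUs with no annotated member keep orientation
    'unassigned'.
    """
    replicon = pooled.replicon
    genes = [g for g in genes if g.replicon == replicon]
    out: list[TranscriptionalUnit] = []
    v = pooled.values
    for raw in sorted(tus, key=lambda t: t.start):
        members = [g for g in genes if g.start < raw.end and g.end > raw.start]
        strands = {g.strand for g in members}
        if not members:
            out.append(TranscriptionalUnit(
                replicon=replicon, start=raw.start, end=raw.end,
                orientation="unassigned", flags=set(raw.flags),
                mean_coverage=raw.mean_coverage))
            continue
        if len(strands) == 1:
            tu = TranscriptionalUnit(
                replicon=replicon, start=raw.start, end=raw.end,
                orientation="F" if members[0].strand == "+" else "R",
                member_gene_ids=[g.gene_id for g in
                                 sorted(members, key=lambda g: g.start)],
                flags=set(raw.flags), mean_coverage=raw.mean_coverage)
            _boundary_flags(tu, members)
            out.append(tu)
            continue
        # mixed strands: split at every junction between strand blocks
        blocks = _strand_blocks(members)
        n = len(blocks)
        for j, block in enumerate(blocks):
            frag_start = raw.start if j == 0 else blocks[j][0].start
            frag_end = raw.end if j == n - 1 else block[-1].end
            flags = set(raw.flags)
            if j > 0:
                left_strand = blocks[j - 1][0].strand
                flags.add(SPLIT_CONVERGENT if left_strand == "+" else SPLIT_DIVERGENT)
            if j < n - 1:
                flags.add(SPLIT_CONVERGENT if block[0].strand == "+" else SPLIT_DIVERGENT)
            tu = TranscriptionalUnit(
                replicon=replicon, start=frag_start, end=frag_end,
                orientation="F" if block[0].strand == "+" else "R",
                member_gene_ids=[g.gene_id for g in block],
                flags=flags,
                mean_coverage=float(v[frag_start:frag_end].mean()))
            _boundary_flags(tu, block)
            out.append(tu)
    return out


# ---------------------------------------------------------------------------
# UTRs and operon sizes


def compute_utrs(tus: list[TranscriptionalUnit],
                 genes: list[GeneRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TU 5'/3' UTR lengths and the operon-size histogram.

    The 5' UTR is the distance, in the direction of transcription, from the
    TU start to the first member gene's start; the 3' UTR runs from the last
    member gene's stop to the TU end. A UTR is reported as missing (NaN)
    when the corresponding boundary is flagged (TSS/TES inside gene, or set
    by splitting rather than observed from coverage).
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for tu in tus:
        if tu.orientation not in ("F", "R") or not tu.member_gene_ids:
            continue
        members = [by_id[g] for g in tu.member_gene_ids]
        lo = min(g.start for g in members)
        hi = max(g.end for g in members)
        if tu.orientation == "F":
            utr5, utr3 = lo - tu.start, tu.end - hi
            first = min(members, key=lambda g: g.start).gene_id
            last = max(members, key=lambda g: g.end).gene_id
        else:
            utr5, utr3 = tu.end - hi, lo - tu.start
            first = max(members, key=lambda g: g.end).gene_id
            last = min(members, key=lambda g: g.start).gene_id
        split = {SPLIT_CONVERGENT, SPLIT_DIVERGENT} & tu.flags
        if TSS_INSIDE_GENE in tu.flags or split:
            utr5 = np.nan
        if TES_INSIDE_GENE in tu.flags or split:
            utr3 = np.nan
        rows.append({"tu_id": tu.tu_id, "first_gene": first, "last_gene": last,
                     "utr5": utr5, "utr3": utr3, "n_genes": tu.n_members})
    utr_df = pd.DataFrame(rows, columns=["tu_id", "first_gene", "last_gene",
                                         "utr5", "utr3", "n_genes"])
    if len(utr_df):
        hist = (utr_df.groupby("n_genes").size().rename("n_tus")
                .reset_index())
    else:
        hist = pd.DataFrame(columns=["n_genes", "n_tus"])
    return utr_df, hist


def tus_to_frame(tus: list[TranscriptionalUnit]) -> pd.DataFrame:
    """Flatten TUs for TSV output (coordinates printed 1-based inclusive)."""
    return pd.DataFrame([
        {"tu_id": tu.tu_id, "replicon": tu.replicon,
         "start": tu.start + 1, "end": tu.end,
         "orientation": tu.orientation,
         "members": ",".join(tu.member_gene_ids),
         "flags": ",".join(sorted(tu.flags)),
         "mean_coverage": tu.mean_coverage}
        for tu in tus
    ])


def call_transcript_units(tracks: list[CoverageTrack], genes: list[GeneRecord],
                          sequence: str | None = None, min_mean: float = 5.0,
                          merge_gap: int = 5, k: int = 52,
                          ) -> list[TranscriptionalUnit]:
    """Full TU-calling stage: pool, threshold, gap-fuse, k-mer-fuse, associate."""
    pooled = pool_coverage(tracks)
    raw = call_raw_tus(pooled, min_mean=min_mean, merge_gap=merge_gap)
    if sequence is not None and len(sequence) >= k:
        flagged = map_nonunique_kmers(sequence, k=k)
        raw = fuse_by_kmer(raw, flagged)
    return associate_genes(raw, genes, pooled)
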