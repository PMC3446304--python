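"""TU calling: thresholding, gap fusing, k-mer fusing, gene association."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decaymap.models import (
    FUSED_BY_KMER,
    SPLIT_CONVERGENT,
    SPLIT_DIVERGENT,
    TES_INSIDE_GENE,
    TSS_INSIDE_GENE,
    CoverageTrack,
    GeneRecord,
)
from decaymap.simulate import (
    SimConfig,
    assign_decay_params,
    make_genome,
    simulate_coverage,
)
from decaymap.transcript_units import (
    RawTU,
    associate_genes,
    call_raw_tus,
    call_transcript_units,
    compute_utrs,
    fuse_by_kmer,
    map_nonunique_kmers,
    pool_coverage,
)


def track(values, replicon="chr") -> CoverageTrack:
    return CoverageTrack(replicon=replicon, values=np.asarray(values, float))


# ---------------------------------------------------------------------------
# oracles


def call_raw_tus_oracle(values, min_mean=5.0, merge_gap=5):
    """Explicit run/gap enumeration, position by position."""
    stretches = []
    start = None
    for i, v in enumerate(list(values) + [0.0]):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            stretches.append((start, i))
            start = None
    kept = [(s, e) for s, e in stretches
            if sum(values[s:e]) / (e - s) > min_mean]
    fused = []
    for s, e in kept:
        if fused and s - fused[-1][1] <= merge_gap:
            fused[-1] = [fused[-1][0], e]
        else:
            fused.append([s, e])
    return [(s, e) for s, e in fused]


def nonunique_kmers_oracle(seq, k):
    """All-pairs window comparison, then per-position all-windows check."""
    comp = str.maketrans("ACGT", "TGCA")
    n = len(seq)
    windows = [seq[i:i + k] for i in range(n - k + 1)]
    dup = []
    for i, w in enumerate(windows):
        rc = w.translate(comp)[::-1]
        count = sum(1 for x in windows if x == w or x == rc)
        dup.append(count > 1)
    flagged = []
    for p in range(n):
        covering = [dup[i] for i in range(max(0, p - k + 1),
                                          min(p, n - k) + 1)]
        flagged.append(bool(covering) and all(covering))
    runs, start = [], None
    for i, f in enumerate(flagged + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    return runs


# ---------------------------------------------------------------------------
# pooling


class TestPoolCoverage:
    def test_per_base_sum(self):
        pooled = pool_coverage([track([5, 0]), track([0, 5])])
        np.testing.assert_array_equal(pooled.values, [5, 5])

    def test_single_track_identity(self):
        pooled = pool_coverage([track([1, 2, 3])])
        np.testing.assert_array_equal(pooled.values, [1, 2, 3])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            pool_coverage([])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pool_coverage([track([1, 2]), track([1, 2, 3])])


# ---------------------------------------------------------------------------
# raw TU calling


class TestCallRawTus:
    def test_single_covered_stretch(self):
        tus = call_raw_tus(track([0, 0, 10, 10, 10, 0, 0]))
        assert [(t.start, t.end) for t in tus] == [(2, 5)]

    def test_gap_of_five_fuses_six_does_not(self):
        five = [10] * 10 + [0] * 5 + [10] * 10
        six = [10] * 10 + [0] * 6 + [10] * 10
        assert len(call_raw_tus(track(five))) == 1
        assert len(call_raw_tus(track(six))) == 2

    def test_mean_exactly_five_is_rejected(self):
        assert call_raw_tus(track([4.0] * 20)) == []
        assert call_raw_tus(track([5.0] * 20)) == []
        assert len(call_raw_tus(track([5.001] * 20))) == 1

    def test_fused_mean_recomputed_over_full_span(self):
        v = [10] * 10 + [0] * 4 + [10] * 10
        (tu,) = call_raw_tus(track(v))
        assert tu.mean_coverage == pytest.approx(200 / 24)

    def test_matches_oracle_on_random_tracks(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 500))
            values = rng.poisson(rng.uniform(0, 12), size=n).astype(float)
            values[rng.random(n) < 0.4] = 0.0
            got = [(t.start, t.end) for t in call_raw_tus(track(values))]
            assert got == call_raw_tus_oracle(values)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(values=st.lists(st.integers(0, 15), min_size=1, max_size=120),
           gap_small=st.integers(0, 6), gap_extra=st.integers(0, 6))
    def test_raising_merge_gap_never_increases_count(self, values, gap_small,
                                                     gap_extra):
        t = track(np.asarray(values, float))
        n_small = len(call_raw_tus(t, merge_gap=gap_small))
        n_large = len(call_raw_tus(t, merge_gap=gap_small + gap_extra))
        assert n_large <= n_small

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(values=st.lists(st.integers(0, 15), min_size=1, max_size=120),
           lo=st.floats(0, 8), extra=st.floats(0, 8))
    def test_raising_min_mean_never_increases_count_unfused(self, values, lo,
                                                            extra):
        # without gap fusing a stricter mean threshold only removes TUs
        t = track(np.asarray(values, float))
        n_lo = len(call_raw_tus(t, min_mean=lo, merge_gap=0))
        n_hi = len(call_raw_tus(t, min_mean=lo + extra, merge_gap=0))
        assert n_hi <= n_lo

    def test_every_tu_mean_above_threshold_before_splitting(self, rng):
        for _ in range(50):
            values = rng.poisson(6, size=400).astype(float)
            values[rng.random(400) < 0.5] = 0.0
            for tu in call_raw_tus(track(values), merge_gap=0):
                assert tu.mean_coverage > 5.0


# ---------------------------------------------------------------------------
# non-unique k-mers


class TestMapNonuniqueKmers:
    def test_random_sequence_has_no_repeats(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert map_nonunique_kmers(seq, k=52) == []

    def test_tandem_duplication_flags_both_copies(self, rng):
        k = 52
        unit = "".join(rng.choice(list("ACGT"), size=200))
        left = "".join(rng.choice(list("ACGT"), size=300))
        right = "".join(rng.choice(list("ACGT"), size=300))
        seq = left + unit + unit + right
        flagged = map_nonunique_kmers(seq, k=k)
        # interior of each copy is unmappable; k-mers spanning the copy
        # junction occur once, so the two flagged runs stay separate
        assert len(flagged) == 2
        (s1, e1), (s2, e2) = flagged
        assert 300 < s1 < e1 <= 500 and 500 <= s2 < e2 < 700

    def test_reverse_complement_counts_as_duplicate(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        unit = "".join(rng.choice(list("ACGT"), size=120))
        seq = unit + "".join(rng.choice(list("ACGT"), size=200)) \
            + unit.translate(comp)[::-1]
        assert map_nonunique_kmers(seq, k=52) != []

    @pytest.mark.parametrize("k", [8, 15])
    def test_matches_brute_force_on_toy_genomes(self, rng, k):
        for _ in range(10):
            n = int(rng.integers(k + 5, 120))
            seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4],
                                     size=n))
            assert map_nonunique_kmers(seq, k=k) == nonunique_kmers_oracle(seq, k)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            map_nonunique_kmers("ACGT", k=52)


class TestFuseByKmer:
    def test_facing_ends_in_one_region_fuse(self):
        tus = [RawTU(0, 100, 10.0), RawTU(150, 250, 10.0)]
        fused = fuse_by_kmer(tus, [(90, 160)])
        assert len(fused) == 1
        assert fused[0].start == 0 and fused[0].end == 250
        assert FUSED_BY_KMER in fused[0].flags

    def test_unflagged_gap_unchanged(self):
        tus = [RawTU(0, 100, 10.0), RawTU(150, 250, 10.0)]
        assert len(fuse_by_kmer(tus, [(300, 400)])) == 2

    def test_chain_through_abutting_regions_reaches_fixpoint(self):
        tus = [RawTU(0, 100, 10.0), RawTU(150, 250, 10.0),
               RawTU(300, 400, 10.0)]
        # two directly abutting flagged runs bridge all three TUs
        fused = fuse_by_kmer(tus, [(90, 200), (200, 310)])
        assert len(fused) == 1
        assert (fused[0].start, fused[0].end) == (0, 400)

    def test_only_one_end_in_region_does_not_fuse(self):
        tus = [RawTU(0, 100, 10.0), RawTU(150, 250, 10.0)]
        assert len(fuse_by_kmer(tus, [(90, 120)])) == 2


# ---------------------------------------------------------------------------
# gene association and splitting


def gene(gene_id, start, end, strand, replicon="chr"):
    return GeneRecord(gene_id=gene_id, replicon=replicon, start=start,
                      end=end, strand=strand)


class TestAssociateGenes:
    def test_two_same_strand_genes_one_tu(self):
        pooled = track(np.full(1000, 10.0))
        tus = associate_genes([RawTU(100, 900, 10.0)],
                              [gene("a", 150, 400, "+"),
                               gene("b", 450, 850, "+")], pooled)
        assert len(tus) == 1
        assert tus[0].member_gene_ids == ["a", "b"]
        assert tus[0].orientation == "F"
        assert tus[0].flags == set()

    def test_convergent_split_sets_tes_at_gene_stops(self):
        pooled = track(np.full(1000, 10.0))
        tus = associate_genes([RawTU(100, 900, 10.0)],
                              [gene("a", 150, 400, "+"),
                               gene("b", 500, 850, "-")], pooled)
        assert len(tus) == 2
        left, right = tus
        assert left.end == 400  # (+) gene's annotated stop
        assert right.start == 500  # (-) gene's annotated stop
        assert SPLIT_CONVERGENT in left.flags
        assert SPLIT_CONVERGENT in right.flags

    def test_divergent_split_sets_tss_at_gene_starts(self):
        pooled = track(np.full(1000, 10.0))
        tus = associate_genes([RawTU(100, 900, 10.0)],
                              [gene("a", 150, 400, "-"),
                               gene("b", 500, 850, "+")], pooled)
        left, right = tus
        assert left.end == 400  # (-) gene's annotated start = its 5' end
        assert right.start == 500
        assert SPLIT_DIVERGENT in left.flags and SPLIT_DIVERGENT in right.flags

    def test_tss_inside_gene_flag(self):
        pooled = track(np.full(1000, 10.0))
        (tu,) = associate_genes([RawTU(200, 900, 10.0)],
                                [gene("a", 150, 400, "+")], pooled)
        assert TSS_INSIDE_GENE in tu.flags

    def test_tes_inside_gene_flag_on_reverse(self):
        pooled = track(np.full(1000, 10.0))
        (tu,) = associate_genes([RawTU(200, 900, 10.0)],
                                [gene("a", 150, 400, "-")], pooled)
        assert TES_INSIDE_GENE in tu.flags

    def test_no_annotation_keeps_unassigned(self):
        pooled = track(np.full(100, 10.0))
        (tu,) = associate_genes([RawTU(10, 90, 10.0)], [], pooled)
        assert tu.orientation == "unassigned"
        assert tu.tu_id.endswith("_U")

    def test_splitting_conserves_genes(self, rng):
        """Multiset of member genes is unchanged by splitting."""
        pooled = track(np.full(5000, 10.0))
        genes = []
        pos = 100
        for i in range(12):
            length = int(rng.integers(100, 300))
            genes.append(gene(f"g{i}", pos, pos + length,
                              rng.choice(["+", "-"])))
            pos += length + int(rng.integers(10, 50))
        tus = associate_genes([RawTU(50, pos + 50, 10.0)], genes, pooled)
        members = sorted(gid for tu in tus for gid in tu.member_gene_ids)
        assert members == sorted(g.gene_id for g in genes)

    def test_tu_id_uses_one_based_inclusive_coordinates(self):
        pooled = track(np.full(1000, 10.0))
        (tu,) = associate_genes([RawTU(99, 900, 10.0)],
                                [gene("a", 150, 400, "-")], pooled)
        assert tu.tu_id == "TU_100-900_R"


class TestComputeUtrs:
    def test_forward_utrs(self):
        pooled = track(np.full(400, 10.0))
        tus = associate_genes([RawTU(100, 400, 10.0)],
                              [gene("a", 150, 300, "+")], pooled)
        utr, hist = compute_utrs(tus, [gene("a", 150, 300, "+")])
        assert utr.loc[0, "utr5"] == 50
        assert utr.loc[0, "utr3"] == 100
        assert hist.loc[0, "n_genes"] == 1 and hist.loc[0, "n_tus"] == 1

    def test_reverse_utrs(self):
        pooled = track(np.full(400, 10.0))
        g = gene("a", 150, 300, "-")
        tus = associate_genes([RawTU(100, 400, 10.0)], [g], pooled)
        utr, _ = compute_utrs(tus, [g])
        assert utr.loc[0, "utr5"] == 100
        assert utr.loc[0, "utr3"] == 50

    def test_flagged_boundary_suppresses_utr(self):
        pooled = track(np.full(400, 10.0))
        g = gene("a", 50, 300, "+")
        tus = associate_genes([RawTU(100, 400, 10.0)], [g], pooled)
        utr, _ = compute_utrs(tus, [g])
        assert np.isnan(utr.loc[0, "utr5"])
        assert utr.loc[0, "utr3"] == 100


# ---------------------------------------------------------------------------
# end-to-end operon recovery on synthetic data


class TestOperonRecovery:
    def test_planted_operons_recovered_with_exact_members(self):
        """>= 95% of well-covered planted operons come back intact."""
        cfg = SimConfig(n_operons=50, seed=21, expression_median=2000.0,
                        expression_sigma=0.3, n_replicates=1)
        genes, seqs, spans = make_genome(cfg)
        params = assign_decay_params(genes, cfg)
        tracks = simulate_coverage(genes, params, cfg, sequences=seqs,
                                   operon_spans=spans)
        flat = [t for ts in tracks.values() for t in ts]
        tus = call_transcript_units(flat, genes)
        called_members = {tuple(tu.member_gene_ids) for tu in tus}
        by_op: dict[str, list] = {}
        for g in genes:
            by_op.setdefault(g.operon_id, []).append(g)
        recovered = 0
        for members in by_op.values():
            ids = tuple(g.gene_id for g in
                        sorted(members, key=lambda g: g.start))
            recovered += ids in called_members
        assert recovered / len(by_op) >= 0.95
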