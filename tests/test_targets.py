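"""Target assignment by the 3 kb TSS rule and co-binding statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from floranet.io import GeneRecord, GenomicInterval, PeakRecord
from floranet.targets import (
    assign_targets,
    classify_targets,
    hypergeometric_coregulation,
    jaccard_cobinding,
)
from tests.oracles import hypergeom_sf_oracle


def peak(chrom, start, end, tf="SEP3", stage="S4", score=1.0, summit=None):
    return PeakRecord(
        GenomicInterval(chrom, start, end), tf, stage, score, summit
    )


def gene(gene_id, chrom, start, end, strand="+", **kw):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end, strand), **kw)


class TestAssignTargets:
    def test_summit_at_tss_gives_distance_zero(self):
        g = gene("g1", "chr1", 10_000, 12_000)
        p = peak("chr1", 9_900, 10_100, summit=100)  # summit at 10,000
        (a,) = assign_targets([p], [g])
        assert a.gene_id == "g1" and a.distance == 0

    def test_window_boundary_inclusive_at_3000(self):
        g = gene("g1", "chr1", 10_000, 12_000)
        at_3000 = peak("chr1", 6_900, 7_100, summit=100)  # ref 7000
        beyond = peak("chr1", 6_899, 7_099, summit=100)  # ref 6999
        assert len(assign_targets([at_3000], [g])) == 1
        assert len(assign_targets([beyond], [g])) == 0

    def test_distance_sign_is_strand_aware(self):
        plus = gene("gp", "chr1", 10_000, 12_000, "+")
        minus = gene("gm", "chr2", 10_000, 12_000, "-")
        # 500 bp to the left of the + TSS: upstream, negative
        p1 = peak("chr1", 9_400, 9_600, summit=100)
        (a1,) = assign_targets([p1], [plus])
        assert a1.distance == -500
        # 500 bp to the right of the - TSS (at 11,999): upstream on - strand
        p2 = peak("chr2", 12_399, 12_599, summit=100)
        (a2,) = assign_targets([p2], [minus])
        assert a2.distance == -500

    def test_max_score_min_distance_aggregation(self):
        g = gene("g1", "chr1", 10_000, 12_000)
        near_low = peak("chr1", 9_950, 10_150, score=2.0, summit=100)  # d=50
        far_high = peak("chr1", 8_900, 9_100, score=9.0, summit=100)  # d=-1000
        (a,) = assign_targets([near_low, far_high], [g])
        assert a.score == 9.0 and a.distance == 50

    def test_invariant_to_peak_order(self):
        g = [gene(f"g{i}", "chr1", 10_000 * i, 10_000 * i + 2000) for i in range(1, 5)]
        rng = np.random.default_rng(0)
        peaks = [
            peak("chr1", int(s), int(s) + 200, score=float(sc))
            for s, sc in zip(
                rng.integers(8_000, 45_000, 30), rng.uniform(1, 9, 30)
            )
        ]
        fwd = assign_targets(peaks, g)
        rev = assign_targets(peaks[::-1], g)
        assert fwd == rev

    def test_one_peak_may_hit_multiple_genes(self):
        close = [
            gene("gA", "chr1", 10_000, 11_000),
            gene("gB", "chr1", 12_000, 13_000),
        ]
        p = peak("chr1", 10_900, 11_100, summit=100)  # ref 11,000
        hits = {a.gene_id for a in assign_targets([p], close)}
        assert hits == {"gA", "gB"}

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            assign_targets([], [], window=0)

    def test_sep3_mir319a_circuit_fixture(self):
        """SEP3 peaks upstream of MIR319a, TCP4 and TCP10 hit all three loci."""
        genes = [
            gene("MIR319a", "chr2", 50_000, 50_500, "+",
                 gene_class="miRNA_precursor"),
            gene("TCP4", "chr3", 80_000, 82_000, "+", is_tf=True),
            gene("TCP10", "chr2", 90_000, 92_000, "-", is_tf=True),
        ]
        peaks = [
            peak("chr2", 49_000, 49_400, summit=200),   # 1.2 kb upstream
            peak("chr3", 79_400, 79_800, summit=200),   # 0.4 kb upstream
            peak("chr2", 93_000, 93_400, summit=200),   # upstream on - strand
        ]
        hits = {a.gene_id for a in assign_targets(peaks, genes)}
        assert hits == {"MIR319a", "TCP4", "TCP10"}


class TestClassifyTargets:
    def test_three_way_split(self):
        genes = [
            gene("t1", "chr1", 10_000, 12_000, is_tf=True),
            gene("m1", "chr1", 20_000, 21_000, gene_class="miRNA_precursor"),
            gene("o1", "chr1", 30_000, 32_000),
        ]
        peaks = [
            peak("chr1", s, s + 200, summit=100)
            for s in (9_900, 19_900, 29_900)
        ]
        counts = classify_targets(assign_targets(peaks, genes), genes)
        assert counts["SEP3"] == {"TF": 1, "MIR": 1, "other": 1}

    def test_empty_assignments(self):
        assert classify_targets([], []) == {}

    def test_unknown_gene_rejected(self):
        genes = [gene("g1", "chr1", 0, 100)]
        from floranet.targets import TargetAssignment

        bad = [TargetAssignment("SEP3", "S4", "ghost", 0, 1.0)]
        with pytest.raises(KeyError):
            classify_targets(bad, genes)

    def test_class_fractions_track_planted_annotation(self):
        # 10% of 300 target genes carry the TF flag
        rng = np.random.default_rng(1)
        genes, peaks = [], []
        n_tf = 0
        for i in range(300):
            is_tf = bool(rng.random() < 0.1)
            n_tf += is_tf
            genes.append(
                gene(f"g{i:03d}", "chr1", 10_000 * i, 10_000 * i + 2000,
                     is_tf=is_tf)
            )
            peaks.append(peak("chr1", 10_000 * i + 400, 10_000 * i + 600,
                              summit=100))
        counts = classify_targets(assign_targets(peaks, genes), genes)["SEP3"]
        assert counts["TF"] == n_tf
        assert counts["TF"] + counts["other"] == 300


class TestJaccard:
    def test_identity_disjoint_and_partial(self):
        a = [peak("chr1", 0, 100)]
        assert jaccard_cobinding(a, a) == 1.0
        b = [peak("chr1", 500, 600)]
        assert jaccard_cobinding(a, b) == 0.0
        c = [peak("chr1", 50, 150)]
        assert jaccard_cobinding(a, c) == pytest.approx(50 / 150)

    def test_merging_before_computation(self):
        # overlapping fragments merge to [0, 100) so jaccard vs [0,100) is 1
        frags = [peak("chr1", 0, 60), peak("chr1", 40, 100)]
        whole = [peak("chr1", 0, 100)]
        assert jaccard_cobinding(frags, whole) == 1.0

    def test_empty_sets_undefined(self):
        with pytest.raises(ValueError):
            jaccard_cobinding([], [])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)),
            min_size=1, max_size=12,
        ),
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)),
            min_size=1, max_size=12,
        ),
    )
    def test_bounds_and_symmetry(self, iv_a, iv_b):
        pa = [peak("chr1", s, s + w) for s, w in iv_a]
        pb = [peak("chr1", s, s + w) for s, w in iv_b]
        j1 = jaccard_cobinding(pa, pb)
        j2 = jaccard_cobinding(pb, pa)
        assert 0.0 <= j1 <= 1.0
        assert j1 == pytest.approx(j2)


class TestHypergeometric:
    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        a = {"g0", "g1"}
        b = {"g5", "g6"}
        assert hypergeometric_coregulation(a, b, universe) == pytest.approx(1.0)

    def test_full_containment_small_case(self):
        # all 5 of b drawn inside a of size 5 from N=20: p = 1/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        p = hypergeometric_coregulation(a, a, universe)
        from math import comb

        assert p == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_matches_tail_sum_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(30)}
        b = {f"g{i}" for i in range(21, 51)}  # overlap 9
        p = hypergeometric_coregulation(a, b, universe)
        assert p == pytest.approx(hypergeom_sf_oracle(9, 100, 30, 30), rel=1e-12)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_coregulation({"x"}, {"y"}, {"y"})

    def test_library_path_equals_oracle_on_grid(self):
        """scipy's survival function vs log-free rational tail sums."""
        for N, K, n, k in [
            (50, 10, 10, 3),
            (50, 25, 25, 12),
            (40, 5, 30, 4),
            (30, 15, 15, 15),
            (100, 50, 50, 25),
        ]:
            lib = float(stats.hypergeom.sf(k - 1, N, K, n))
            oracle = hypergeom_sf_oracle(k, N, K, n)
            assert lib == pytest.approx(oracle, rel=1e-10)
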