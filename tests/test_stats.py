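"""Overlap primitives, Monte-Carlo fold enrichment against enumeration
oracles, hypergeometric exactness, and association-test behavior."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from sirtchip.genome import GenomeLayout, Interval
from sirtchip.peaks import Peak, PeakSet
from sirtchip.stats import (
    ContainmentError,
    PartitionError,
    PlacementError,
    fold_enrichment_random,
    geneset_overlap_test,
    interval_overlap,
    multiway_overlap,
    regulation_association_test,
)


class TestIntervalOverlap:
    def test_identical_sets(self):
        ivs = [Interval("c", 0, 10), Interval("c", 20, 35)]
        bp, na, nb = interval_overlap(ivs, list(ivs))
        assert (bp, na, nb) == (25, 2, 2)

    def test_disjoint_sets(self):
        a = [Interval("c", 0, 10)]
        b = [Interval("c", 10, 20)]
        assert interval_overlap(a, b) == (0, 0, 0)

    def test_partial_overlap_arithmetic(self):
        a = [Interval("c", 0, 10)]
        b = [Interval("c", 5, 15)]
        assert interval_overlap(a, b) == (5, 1, 1)

    def test_within_set_overlaps_merged_first(self):
        a = [Interval("c", 0, 10), Interval("c", 5, 12)]
        b = [Interval("c", 0, 12)]
        bp, na, nb = interval_overlap(a, b)
        assert bp == 12  # union of A is [0, 12), not 10 + 7
        assert (na, nb) == (2, 1)


class TestFoldEnrichment:
    LAYOUT = GenomeLayout(("c",), (100,))

    def toy(self, n_perm=2000, seed=0):
        peaks = PeakSet("f", [Peak(Interval("c", 45, 55), 0.9)])
        features = [Interval("c", 45, 55)]
        return fold_enrichment_random(
            peaks, features, self.LAYOUT, mode="feature_count",
            n_perm=n_perm, seed=seed,
        )

    def test_enumeration_oracle_on_100bp_toy(self):
        # 91 placements of a 10 bp peak; 19 hit the 10 bp feature at [45, 55)
        hits = sum(
            1 for s in range(91) if s < 55 and 45 < s + 10
        )
        assert hits == 19
        res = self.toy()
        assert res.observed == 1.0
        se = res.null_sd / np.sqrt(res.n_perm)
        assert abs(res.expected - 19 / 91) <= 3 * se
        assert res.fold == pytest.approx(91 / 19, rel=0.10)

    def test_reproducible_under_seed(self):
        r1, r2 = self.toy(n_perm=300, seed=5), self.toy(n_perm=300, seed=5)
        assert (r1.expected, r1.empirical_p, r1.null_sd) == (
            r2.expected, r2.empirical_p, r2.null_sd)

    def test_saturated_genome_gives_fold_one(self):
        features = [Interval("c", 0, 100)]
        peaks = PeakSet("f", [Peak(Interval("c", 10, 20), 0.9)])
        res = fold_enrichment_random(peaks, features, self.LAYOUT,
                                     mode="feature_count", n_perm=200, seed=1)
        assert res.fold == 1.0
        assert res.empirical_p == 1.0

    def test_empty_null_overlap_flags_infinite_fold(self):
        layout = GenomeLayout(("c", "d"), (100, 100))
        peaks = PeakSet("f", [Peak(Interval("c", 0, 50), 0.9)])
        features = [Interval("d", 0, 50)]  # never reachable: peak stays on c
        res = fold_enrichment_random(peaks, features, layout,
                                     mode="feature_count", n_perm=200, seed=1)
        assert res.saturated and res.fold == float("inf")

    def test_peak_longer_than_chromosome_rejected(self):
        layout = GenomeLayout(("c", "d"), (100, 30))
        peaks = PeakSet("f", [Peak(Interval("d", 0, 31), 0.9)])
        with pytest.raises(PlacementError):
            fold_enrichment_random(peaks, [Interval("c", 0, 10)], layout,
                                   n_perm=200, seed=0)

    def test_bp_mode_against_exhaustive_enumeration(self):
        # single 10 bp peak, feature [40, 60): enumerate all 91 placements
        layout = self.LAYOUT
        feature = (40, 60)
        exact = np.array(
            [max(0, min(s + 10, feature[1]) - max(s, feature[0])) for s in range(91)]
        )
        peaks = PeakSet("f", [Peak(Interval("c", 40, 50), 0.9)])
        res = fold_enrichment_random(peaks, [Interval("c", *feature)], layout,
                                     mode="bp", n_perm=4000, seed=2)
        se = res.null_sd / np.sqrt(res.n_perm)
        assert res.observed == 10.0
        assert abs(res.expected - exact.mean()) <= 3 * se

    def test_uniform_peaks_give_unit_fold_on_average(self):
        layout = GenomeLayout(("c",), (10_000,))
        features = [Interval("c", s, s + 50) for s in range(0, 10_000, 500)]
        rng = np.random.default_rng(3)
        folds = []
        for _ in range(30):
            starts = rng.integers(0, 10_000 - 100, size=10)
            peaks = PeakSet("f", [Peak(Interval("c", int(s), int(s) + 100), 0.9)
                                  for s in starts])
            res = fold_enrichment_random(peaks, features, layout,
                                         mode="feature_count", n_perm=200,
                                         seed=int(rng.integers(2**31)))
            folds.append(res.fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)


class TestHypergeometric:
    def test_forced_total_overlap_has_p_one(self):
        u = {f"g{i}" for i in range(6)}
        res = geneset_overlap_test(u, u, u)
        assert res.n_intersection == 6 and res.p_value == pytest.approx(1.0)

    def test_enumeration_example_universe_four(self):
        u = {"a", "b", "c", "d"}
        res = geneset_overlap_test({"a", "b"}, {"a", "b"}, u)
        assert res.p_value == pytest.approx(1 / 6, abs=1e-12)

    def test_disjoint_sets_have_p_one(self):
        u = {f"g{i}" for i in range(10)}
        res = geneset_overlap_test({"g0", "g1"}, {"g5", "g6"}, u)
        assert res.p_value == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ContainmentError):
            geneset_overlap_test({"x"}, {"a"}, {"a", "b"})

    @pytest.mark.parametrize("M", [5, 8])
    def test_matches_combinatorial_enumeration(self, M):
        universe = [f"g{i}" for i in range(M)]
        for K in range(M + 1):
            B = set(universe[:K])
            for N in range(M + 1):
                for k in range(max(0, N + K - M), min(K, N) + 1):
                    A = set(universe[:k]) | set(universe[K : K + N - k])
                    exact = sum(
                        Fraction(comb(K, j) * comb(M - K, N - j), comb(M, N))
                        for j in range(k, min(K, N) + 1)
                    )
                    res = geneset_overlap_test(A, B, set(universe))
                    assert res.n_intersection == k
                    assert abs(res.p_value - float(exact)) < 1e-12


class TestMultiway:
    def test_identical_sets_fill_only_triple_region(self):
        s = {f"g{i}" for i in range(4)}
        u = s | {"x", "y"}
        venn = multiway_overlap({"A": s, "B": s, "C": s}, u)
        assert venn.region_counts["A&B&C"] == 4
        assert sum(v for k, v in venn.region_counts.items() if k != "A&B&C") == 0

    def test_disjoint_sets_fill_only_singletons(self):
        u = {f"g{i}" for i in range(9)}
        sets = {"A": {"g0", "g1"}, "B": {"g3", "g4"}, "C": {"g6"}}
        venn = multiway_overlap(sets, u)
        assert venn.region_counts["A"] == 2
        assert venn.region_counts["B"] == 2
        assert venn.region_counts["C"] == 1
        assert venn.region_counts["A&B"] == 0
        assert venn.region_counts["A&B&C"] == 0

    def test_region_counts_partition_the_union(self):
        rng = np.random.default_rng(0)
        u = [f"g{i}" for i in range(40)]
        sets = {n: set(rng.choice(u, size=15, replace=False)) for n in "ABC"}
        venn = multiway_overlap(sets, set(u))
        assert sum(venn.region_counts.values()) == len(sets["A"] | sets["B"] | sets["C"])
        assert len(venn.pairwise) == 3


class TestRegulationAssociation:
    def setup_method(self):
        self.universe = {f"g{i}" for i in range(100)}
        genes = sorted(self.universe)
        self.classes = {
            g: ("down" if i < 50 else "up" if i < 80 else "unchanged")
            for i, g in enumerate(genes)
        }
        self.genes = genes

    def test_expectation_formula(self):
        bound = set(self.genes[:20])  # 20 genes, all in the down class
        res = regulation_association_test(bound, self.classes, self.universe)
        assert res["down"].observed == 20
        assert res["down"].expected == pytest.approx(10.0)
        assert res["down"].direction == "enriched"
        assert res["up"].observed == 0
        assert res["up"].direction == "depleted"

    def test_extreme_bound_set_minimizes_down_p(self):
        bound = {g for g, c in self.classes.items() if c == "down"}
        res = regulation_association_test(bound, self.classes, self.universe)
        # P(all 50 drawn genes land in the 50-gene class) is the minimum
        min_p = 1 / comb(100, 50)
        assert res["down"].p_two_sided == pytest.approx(min_p, rel=1e-6)
        assert res["up"].direction == "depleted"
        assert res["up"].p_two_sided < 1e-10

    def test_observed_counts_sum_to_bound(self):
        rng = np.random.default_rng(1)
        bound = set(rng.choice(self.genes, size=30, replace=False))
        res = regulation_association_test(bound, self.classes, self.universe)
        assert sum(a.observed for a in res.values()) == 30

    def test_non_partition_rejected(self):
        classes = dict(self.classes)
        classes.pop(self.genes[0])
        with pytest.raises(PartitionError):
            regulation_association_test(set(), classes, self.universe)
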