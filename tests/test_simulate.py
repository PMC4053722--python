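"""Generator contracts: deterministic placement, planted multiplier closed
forms, null-factor indistinguishability, and exact peak-set sharing."""

import io

import numpy as np
import pytest

from sirtchip.genome import AnnotationSet, FeatureAnnotation, GenomeLayout, Interval
from sirtchip.metagene import InsufficientGenesError, MetageneParams, assign_quintiles
from sirtchip.simulate import (
    CapacityError,
    FactorModel,
    PeakSetDesign,
    SyntheticConfig,
    build_toy_genome,
    factor_multiplier,
    resample_reads,
    simulate_expression,
    simulate_factor_reads,
    simulate_peak_sets,
    simulate_regulation_classes,
)

SMALL = SyntheticConfig(
    n_chroms=2, chrom_length=50_000, n_orfs=30, orf_length_range=(400, 900),
    n_pol3=4, n_telomere_clusters=2, rdna_unit_length=2000,
    library_size=20_000, seed=5,
)


def tiled_orf_annots(n: int, orf_len: int = 100) -> AnnotationSet:
    layout = GenomeLayout(("chr1",), (n * (orf_len + 20) + 100,))
    feats = [
        FeatureAnnotation(
            f"g{i:05d}",
            Interval("chr1", i * (orf_len + 20), i * (orf_len + 20) + orf_len, "+"),
            "ORF",
        )
        for i in range(n)
    ]
    return AnnotationSet(layout, feats)


class TestToyGenome:
    def test_zero_feature_case(self):
        cfg = SyntheticConfig(
            n_chroms=1, chrom_length=10_000, n_orfs=0, n_pol3=0,
            n_telomere_clusters=0, rdna_copies=0,
        )
        _, annots = build_toy_genome(cfg)
        assert len(annots) == 0

    def test_same_seed_gives_identical_annotations(self, tmp_path):
        out = []
        for _ in range(2):
            _, annots = build_toy_genome(SMALL)
            p = tmp_path / "a.bed"
            annots.write_bed(p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_features_never_overlap_pairwise(self):
        _, annots = build_toy_genome(SMALL)
        feats = list(annots)
        assert len(annots.orfs) == 30
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                assert not a.interval.overlaps(b.interval), (a, b)

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            build_toy_genome(
                SyntheticConfig(n_chroms=1, chrom_length=5000, n_orfs=50,
                                orf_length_range=(400, 500), rdna_copies=0)
            )

    def test_rdna_unit_carries_copy_metadata(self):
        _, annots = build_toy_genome(SMALL)
        (rdna,) = annots.features_of_class("rDNA_repeat")
        assert rdna.name == "copies=175"


class TestExpression:
    def test_positive_distinct_and_deterministic(self):
        _, annots = build_toy_genome(SMALL)
        e1 = simulate_expression(annots, SMALL)
        e2 = simulate_expression(annots, SMALL)
        assert e1 == e2
        assert set(e1) == {f.feature_id for f in annots.orfs}
        vals = list(e1.values())
        assert all(v > 0 for v in vals)
        assert len(set(vals)) == len(vals)

    def test_median_matches_lognormal_closed_form(self):
        # log-normal with location 0 has median exp(0) = 1
        annots = tiled_orf_annots(10_000)
        cfg = SyntheticConfig(seed=2)
        expr = simulate_expression(annots, cfg)
        assert abs(np.median(list(expr.values())) - 1.0) < 0.1

    def test_too_few_genes_rejected(self):
        annots = tiled_orf_annots(4)
        with pytest.raises(InsufficientGenesError):
            simulate_expression(annots, SyntheticConfig())


@pytest.fixture(scope="module")
def genome():
    layout, annots = build_toy_genome(SMALL)
    expr = simulate_expression(annots, SMALL)
    return layout, annots, expr


class TestFactorMultiplier:

    def test_telomere_decay_closed_form(self, genome):
        layout, annots, expr = genome
        model = FactorModel(
            orf_3prime_fold=1, orf_quintile_scaling=(1,) * 5,
            telomere_fold=10, telomere_decay_bp=1000,
            promoter_fold=1, pol3_fold=1,
        )
        m = factor_multiplier(model, layout, annots, expr)
        tel = annots.features_of_class("telomeric_repeat")[0].interval
        assert np.allclose(m[tel.chrom][tel.start : tel.end], 10.0)
        # 1 kb from the cluster edge: 1 + 9 e^-1
        got = m[tel.chrom][tel.end + 999]
        assert got == pytest.approx(1 + 9 * np.exp(-1), rel=1e-9)

    def test_quintile_scaled_terminal_multiplier(self, genome):
        layout, annots, expr = genome
        model = FactorModel(
            orf_3prime_fold=4, orf_quintile_scaling=(1, 1, 1, 1, 5),
            telomere_fold=1, promoter_fold=1, pol3_fold=1,
        )
        m = factor_multiplier(model, layout, annots, expr)
        q = assign_quintiles(expr, MetageneParams())
        for orf in annots.orfs:
            iv = orf.interval
            three_prime = iv.end - 1 if iv.strand == "+" else iv.start
            five_prime = iv.start if iv.strand == "+" else iv.end - 1
            expected = 20.0 if q[orf.feature_id] == 5 else 4.0
            assert m[iv.chrom][three_prime] == pytest.approx(expected)
            assert m[iv.chrom][five_prime] == pytest.approx(1.0)

    def test_pol3_and_promoter_plateaus(self, genome):
        layout, annots, expr = genome
        model = FactorModel(
            orf_3prime_fold=1, orf_quintile_scaling=(1,) * 5,
            telomere_fold=1, promoter_fold=6, promoter_width=150,
            pol3_fold=10, pol3_width=500,
        )
        m = factor_multiplier(model, layout, annots, expr)
        g = annots.features_of_class("pol3_gene")[0].interval
        mid = (g.start + g.end) // 2
        assert m[g.chrom][mid] == 10.0
        orf = annots.orfs[0].interval
        tss = orf.start if orf.strand == "+" else orf.end - 1
        assert m[orf.chrom][tss] >= 6.0


class TestFactorReads:
    def test_null_factor_indistinguishable_from_input(self):
        layout, annots = build_toy_genome(SMALL)
        expr = simulate_expression(annots, SMALL)
        chip, inp = simulate_factor_reads(
            FactorModel.null(), layout, annots, expr, SMALL
        )
        n1, n2 = chip.total_count, inp.total_count
        z = (n1 - n2) / np.sqrt(n1 + n2)
        assert abs(z) < 4

    def test_multimappers_confined_to_rdna(self):
        layout, annots = build_toy_genome(SMALL)
        expr = simulate_expression(annots, SMALL)
        chip, _ = simulate_factor_reads(FactorModel(), layout, annots, expr, SMALL)
        unit = annots.features_of_class("rDNA_repeat")[0].interval
        multi = chip.subset(chip.is_multimapper)
        assert multi.total_count > 0
        assert np.all(multi.chroms == unit.chrom)
        assert multi.starts.min() >= unit.start
        assert multi.ends.max() <= unit.end
        assert np.all(multi.mapqs == 0)
        assert np.all(chip.subset(~chip.is_multimapper).mapqs == 60)

    def test_determinism_and_resampling(self):
        layout, annots = build_toy_genome(SMALL)
        expr = simulate_expression(annots, SMALL)
        c1, _ = simulate_factor_reads(FactorModel(), layout, annots, expr, SMALL, seed=9)
        c2, _ = simulate_factor_reads(FactorModel(), layout, annots, expr, SMALL, seed=9)
        assert np.array_equal(c1.starts, c2.starts)
        down = resample_reads(c1, 5000, seed=1)
        assert down.total_count == 5000
        # relative chromosome rates preserved within multinomial error
        for chrom in layout.chrom_names:
            p = np.mean(c1.chroms == chrom)
            phat = np.mean(down.chroms == chrom)
            assert abs(phat - p) < 4 * np.sqrt(p * (1 - p) / 5000)


class TestRegulationClasses:
    def test_partition_of_orf_set(self):
        _, annots = build_toy_genome(SMALL)
        expr = simulate_expression(annots, SMALL)
        classes = simulate_regulation_classes(annots, expr, SMALL)
        assert set(classes) == {f.feature_id for f in annots.orfs}
        assert set(classes.values()) <= {"down", "up", "unchanged"}
        n = len(classes)
        assert sum(v == "down" for v in classes.values()) == round(0.3 * n)

    def test_bias_puts_high_expression_in_down_class(self):
        annots = tiled_orf_annots(500)
        cfg = SyntheticConfig(seed=3)
        expr = simulate_expression(annots, cfg)
        classes = simulate_regulation_classes(annots, expr, cfg)
        med = np.median(list(expr.values()))
        down = [g for g, c in classes.items() if c == "down"]
        up = [g for g, c in classes.items() if c == "up"]
        assert np.mean([expr[g] > med for g in down]) > 0.5
        assert np.mean([expr[g] > med for g in up]) < 0.5


class TestPeakSets:
    def test_full_sharing_gives_identical_sets(self):
        layout = GenomeLayout(("chr1",), (100_000,))
        s = simulate_peak_sets(
            PeakSetDesign(n_sets=2, n_peaks=20, shared_fraction=1.0), layout, seed=0
        )
        assert s[0].intervals == s[1].intervals

    def test_designed_pairwise_sharing_is_exact(self):
        layout = GenomeLayout(("chr1", "chr2"), (500_000, 500_000))
        sets = simulate_peak_sets(
            PeakSetDesign(n_sets=3, n_peaks=100, shared_fraction=0.5), layout, seed=1
        )
        for a in range(3):
            assert len(sets[a]) == 100
            for b in range(a + 1, 3):
                shared = set(sets[a].intervals) & set(sets[b].intervals)
                assert len(shared) == 50

    def test_zero_sharing_matches_random_expectation(self):
        # with no designed sharing the two sets are independent, so the
        # observed overlap should equal the re-placement null on average
        from sirtchip.stats import fold_enrichment_random

        layout = GenomeLayout(("chr1",), (300_000,))
        folds = []
        for rep in range(5):
            a, b = simulate_peak_sets(
                PeakSetDesign(n_sets=2, n_peaks=100, peak_length=300,
                              shared_fraction=0.0),
                layout, seed=rep,
            )
            res = fold_enrichment_random(a, b.intervals, layout,
                                         mode="feature_count",
                                         n_perm=300, seed=rep + 50)
            folds.append(res.fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.25)
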