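import numpy as np
import pytest
from scipy import stats

from acemod.phenotyping import hwe_genotype_frequencies
from acemod.protective_screen import exclusive_variants, recurrence_filter
from acemod.synth_cohort import (
    CohortConfig,
    PlantedEffect,
    generate_assay_panel,
    generate_cohort,
    generate_genotype_matrix,
    generate_pqtl_table,
)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_individuals=500, seed=7)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_individuals=500, seed=7))
        b = generate_cohort(CohortConfig(n_individuals=500, seed=8))
        assert a != b

    def test_degenerate_limit_all_100(self):
        cfg = CohortConfig(
            n_individuals=200, assay_cv=0.0, carrier_freq=0.0, d_allele_freq=0.0
        )
        cohort = generate_cohort(cfg)
        assert all(i.id_genotype == "II" for i in cohort)
        assert all(i.true_level == pytest.approx(100.0) for i in cohort)

    def test_noise_free_heterozygote_level(self):
        # one mutant allele at 24% output puts an ID het at exactly 62
        cfg = CohortConfig(n_individuals=4000, assay_cv=0.0, carrier_freq=0.3, seed=5)
        hets = [
            i
            for i in generate_cohort(cfg)
            if i.y215c_copies == 1 and i.id_genotype == "ID"
        ]
        assert hets
        assert all(i.true_level == pytest.approx(62.0) for i in hets)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_individuals=0)
        with pytest.raises(ValueError):
            CohortConfig(d_allele_freq=1.5)
        with pytest.raises(ValueError):
            CohortConfig(carrier_freq=-0.1)

    def test_hwe_convergence(self):
        cfg = CohortConfig(n_individuals=10_000, d_allele_freq=0.5, seed=42)
        cohort = generate_cohort(cfg)
        observed = [
            sum(1 for i in cohort if i.id_genotype == g) for g in ("II", "ID", "DD")
        ]
        freqs = hwe_genotype_frequencies(0.5)
        expected = [freqs[g] * len(cohort) for g in ("II", "ID", "DD")]
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001


class TestAssayPanel:
    @staticmethod
    def _panel(copies, cv=0.0):
        cfg = CohortConfig(
            n_individuals=2000,
            assay_cv=cv,
            carrier_freq=0.4,
            seed=9,
        )
        cohort = generate_assay_panel(generate_cohort(cfg), cfg)
        return [i for i in cohort if i.y215c_copies == copies]

    def test_non_carrier_ratio_unity(self):
        for ind in self._panel(0)[:20]:
            assert ind.assay_5b3 / ind.assay_1g12 == pytest.approx(1.0)

    def test_heterozygote_ratio(self):
        # (1 + 0.24*4.6) / (1 + 0.24) = 1.6968
        expected = (1 + 0.24 * 4.6) / (1 + 0.24)
        for ind in self._panel(1)[:20]:
            assert ind.assay_5b3 / ind.assay_1g12 == pytest.approx(expected)
        assert expected == pytest.approx(1.70, abs=0.01)

    def test_homozygote_ratio_is_multiplier(self):
        for ind in self._panel(2)[:20]:
            assert ind.assay_5b3 / ind.assay_1g12 == pytest.approx(4.6)

    def test_9b9_tracks_total_level_without_noise(self):
        for ind in self._panel(1):
            assert ind.assay_9b9 == pytest.approx(ind.true_level)
            assert ind.assay_1g12 == pytest.approx(ind.true_level)


class TestPqtlTable:
    def test_single_planted_effect(self):
        planted = [PlantedEffect("rsX", "GENE1", beta=-1.2, carrier_fraction=0.02)]
        table = generate_pqtl_table(0, planted, n_samples=10_000, seed=1)
        assert len(table) == 1
        assert table[0].beta == -1.2
        assert table[0].gene == "GENE1"

    def test_strong_planted_effect_passes_bonferroni(self):
        planted = [PlantedEffect("rsY", "GENE2", beta=-1.217, carrier_fraction=0.015)]
        table = generate_pqtl_table(0, planted, n_samples=35_559, seed=1)
        assert table[0].p_value < 3e-7

    def test_null_p_values_uniform(self):
        table = generate_pqtl_table(5000, [], n_samples=10_000, seed=3)
        frac = sum(1 for r in table if r.p_value < 0.05) / len(table)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_deterministic_shuffle(self):
        a = generate_pqtl_table(100, [], n_samples=1000, seed=5)
        b = generate_pqtl_table(100, [], n_samples=1000, seed=5)
        assert [r.variant_id for r in a] == [r.variant_id for r in b]

    def test_negative_n_null_rejected(self):
        with pytest.raises(ValueError):
            generate_pqtl_table(-1, [], n_samples=100, seed=0)

    def test_carrier_fraction_validated(self):
        with pytest.raises(ValueError):
            PlantedEffect("rsZ", "G", beta=1.0, carrier_fraction=1.5)


class TestGenotypeMatrixGeneration:
    def test_planted_truth_recovery(self):
        matrix = generate_genotype_matrix(
            n_high=15,
            n_low=44,
            n_background_variants=100,
            planted_exclusive=42,
            recurrence_range=(3, 5),
            missing_rate=0.0,
            seed=21,
        )
        exclusive = exclusive_variants(matrix)
        recurrent = recurrence_filter(matrix, exclusive)
        recovered = {r.variant_id for r in recurrent}
        planted = {v for v in matrix.variant_ids if v.startswith("ex")}
        assert recovered == planted
        assert len(planted) == 42

    def test_no_planted_means_no_exclusives(self):
        matrix = generate_genotype_matrix(
            n_high=10, n_low=20, n_background_variants=50,
            planted_exclusive=0, missing_rate=0.0, seed=4,
        )
        assert exclusive_variants(matrix) == []

    def test_same_seed_identical_matrix(self):
        kwargs = dict(
            n_high=8, n_low=12, n_background_variants=30,
            planted_exclusive=5, missing_rate=0.1, seed=13,
        )
        a = generate_genotype_matrix(**kwargs)
        b = generate_genotype_matrix(**kwargs)
        assert np.array_equal(a.calls, b.calls)
        assert a.variant_ids == b.variant_ids

    def test_recurrence_exceeding_group_rejected(self):
        with pytest.raises(ValueError):
            generate_genotype_matrix(
                n_high=4, n_low=10, n_background_variants=1,
                planted_exclusive=1, recurrence_range=(3, 5), seed=0,
            )

    def test_missingness_rate_applied(self):
        matrix = generate_genotype_matrix(
            n_high=30, n_low=30, n_background_variants=200,
            planted_exclusive=0, missing_rate=0.1, seed=2,
        )
        frac = (matrix.calls == -1).mean()
        assert frac == pytest.approx(0.1, abs=0.02)
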