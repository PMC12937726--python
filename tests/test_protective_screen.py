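import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from acemod.matrix import GenotypeMatrix
from acemod.protective_screen import (
    CHI2_1DF_MEDIAN,
    AssociationResult,
    RecurrenceWindow,
    allelic_test,
    bonferroni_adjust,
    chi_square_allelic,
    exclusive_variants,
    genomic_inflation,
    recurrence_filter,
    run_protective_screen,
    variant_qc,
)
from conftest import brute_force_exclusive, random_grouped_matrix


def _matrix(calls, n_high):
    calls = np.asarray(calls, dtype=np.int8)
    samples = [f"s{i}" for i in range(calls.shape[0])]
    group = {s: ("high" if i < n_high else "low") for i, s in enumerate(samples)}
    return GenotypeMatrix(
        samples, [f"v{j}" for j in range(calls.shape[1])], calls, group=group
    )


class TestVariantQC:
    def test_high_missingness_removed(self):
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[:3, 0] = -1  # 6% missing
        calls[:, 1] = 1
        m, report = variant_qc(_matrix(calls, 25))
        assert m.variant_ids == ["v1"]
        assert report.n_removed_call_rate == 1

    def test_maf_boundary_inclusive(self):
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[:2, 0] = 1  # MAF = 2/40 = 0.05 exactly
        m, report = variant_qc(_matrix(calls, 10))
        assert m.n_variants == 1
        assert report.n_removed_maf == 0

    def test_below_maf_removed(self):
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[0, 0] = 1  # MAF = 0.025
        m, _ = variant_qc(_matrix(calls, 10))
        assert m.n_variants == 0

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.3, size=(30, 10)).astype(np.int8)
        m, report = variant_qc(_matrix(calls, 15))
        assert m.n_variants == 10
        assert report.n_removed_call_rate == 0

    def test_call_rate_filtered_before_maf(self):
        # a variant failing both is attributed to the call-rate step
        calls = np.full((50, 1), -1, dtype=np.int8)
        _, report = variant_qc(_matrix(calls, 25))
        assert report.n_removed_call_rate == 1
        assert report.n_removed_maf == 0


class TestAllelicChiSquare:
    def test_hand_computed_table(self):
        chi2, p = chi_square_allelic(10, 90, 30, 70)
        assert chi2 == pytest.approx(12.5)
        assert p == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_equal_frequencies_null(self):
        chi2, p = chi_square_allelic(20, 80, 20, 80)
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_margin_convention(self):
        assert chi_square_allelic(0, 0, 5, 5) == (0.0, 1.0)
        assert chi_square_allelic(0, 10, 0, 20) == (0.0, 1.0)

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500),
            st.integers(0, 500), st.integers(0, 500),
        )
    )
    def test_matches_scipy_contingency(self, table):
        a, b, c, d = table
        arr = np.array([[a, b], [c, d]])
        chi2, p = chi_square_allelic(a, b, c, d)
        if arr.sum() == 0 or 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
            assert (chi2, p) == (0.0, 1.0)
        else:
            expected = stats.chi2_contingency(arr, correction=False)
            assert chi2 == pytest.approx(expected.statistic, abs=1e-10)
            assert p == pytest.approx(expected.pvalue, abs=1e-10)

    def test_matrix_test_matches_scalar_formula(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([-1, 0, 1, 2], p=[0.02, 0.5, 0.3, 0.18], size=(40, 50)).astype(np.int8)
        m = _matrix(calls, 15)
        results = allelic_test(m)
        for j, r in enumerate(results):
            hi = calls[:15, j]
            lo = calls[15:, j]
            alt_hi = int(hi[hi > 0].sum())
            alt_lo = int(lo[lo > 0].sum())
            tot_hi = 2 * int((hi != -1).sum())
            tot_lo = 2 * int((lo != -1).sum())
            if (alt_hi + alt_lo) * 2 > tot_hi + tot_lo:
                alt_hi, alt_lo = tot_hi - alt_hi, tot_lo - alt_lo
            chi2, p = chi_square_allelic(alt_hi, tot_hi - alt_hi, alt_lo, tot_lo - alt_lo)
            assert r.chi_square == pytest.approx(chi2, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_monomorphic_variant(self):
        calls = np.zeros((20, 1), dtype=np.int8)
        r = allelic_test(_matrix(calls, 10))[0]
        assert r.chi_square == 0.0
        assert r.p_value == 1.0
        assert r.odds_ratio is None


class TestGenomicInflation:
    def test_unit_lambda_at_null_median(self):
        results = [AssociationResult("v", CHI2_1DF_MEDIAN, 0.5)] * 200
        assert genomic_inflation(results) == pytest.approx(1.0)

    def test_doubled_median(self):
        results = [AssociationResult("v", 2 * CHI2_1DF_MEDIAN, 0.2)] * 200
        assert genomic_inflation(results) == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])

    def test_few_statistics_warn(self, caplog):
        with caplog.at_level("WARNING"):
            genomic_inflation([AssociationResult("v", 1.0, 0.3)] * 10)
        assert any("only" in r.message for r in caplog.records)

    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(5)
        chis = rng.chisquare(1, size=10_000)
        results = [AssociationResult(f"v{i}", float(c), 0.5) for i, c in enumerate(chis)]
        assert 0.9 <= genomic_inflation(results) <= 1.1


class TestBonferroniAdjust:
    def test_simple_scaling(self):
        results = [AssociationResult(f"v{i}", 1.0, 0.01) for i in range(10)]
        adjusted = bonferroni_adjust(results)
        assert adjusted[0].adjusted_p == pytest.approx(0.1)

    def test_capped_at_one(self):
        results = [AssociationResult(f"v{i}", 1.0, 0.5) for i in range(10)]
        assert bonferroni_adjust(results)[0].adjusted_p == 1.0

    def test_single_test_identity(self):
        assert bonferroni_adjust([AssociationResult("v", 1.0, 0.03)])[0].adjusted_p == 0.03


class TestExclusiveVariants:
    def test_high_only_carrier_retained(self):
        calls = np.array([[1], [1], [1], [0], [0]], dtype=np.int8)
        assert exclusive_variants(_matrix(calls, 3)) == ["v0"]

    def test_shared_carrier_removed(self):
        calls = np.array([[1], [0], [0], [1], [0]], dtype=np.int8)
        assert exclusive_variants(_matrix(calls, 3)) == []

    def test_missing_is_not_carriage(self):
        calls = np.array([[1], [0], [0], [-1], [-1]], dtype=np.int8)
        assert exclusive_variants(_matrix(calls, 3)) == ["v0"]

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_grouped_matrix(rng, n_samples=int(rng.integers(2, 30)),
                                  n_variants=int(rng.integers(1, 60)))
        assert exclusive_variants(m) == brute_force_exclusive(m)


class TestRecurrenceFilter:
    def test_window_boundaries(self):
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[:2, 0] = 1   # 2 carriers -> out
        calls[:3, 1] = 1   # 3 carriers -> in
        calls[:6, 2] = 1   # 6 carriers -> out
        m = _matrix(calls, 10)
        kept = recurrence_filter(m, m.variant_ids)
        assert [v.variant_id for v in kept] == ["v1"]
        assert kept[0].carrier_count == 3

    def test_hom_counts_once(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[0, 0] = 2
        calls[1, 0] = 1
        calls[2, 0] = 1
        m = _matrix(calls, 10)
        kept = recurrence_filter(m, m.variant_ids)
        assert kept[0].carrier_count == 3

    def test_wide_window_is_noop(self):
        rng = np.random.default_rng(3)
        m = random_grouped_matrix(rng, n_samples=20, n_variants=30)
        exclusive = exclusive_variants(m)
        wide = recurrence_filter(m, exclusive, RecurrenceWindow(1, 20))
        assert [v.variant_id for v in wide] == exclusive

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_subset_and_window_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        m = random_grouped_matrix(rng, n_samples=15, n_variants=40)
        exclusive = exclusive_variants(m)
        narrow = recurrence_filter(m, exclusive, RecurrenceWindow(3, 5))
        wide = recurrence_filter(m, exclusive, RecurrenceWindow(2, 7))
        assert {v.variant_id for v in narrow} <= {v.variant_id for v in wide}
        assert {v.variant_id for v in wide} <= set(exclusive)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            RecurrenceWindow(5, 3)
        with pytest.raises(ValueError):
            RecurrenceWindow(0, 3)


class TestRunProtectiveScreen:
    def test_full_chain_recovers_planted(self):
        from acemod.synth_cohort import generate_genotype_matrix

        m = generate_genotype_matrix(
            n_high=15, n_low=44, n_background_variants=80,
            planted_exclusive=12, missing_rate=0.0, seed=6,
        )
        _, recurrent, report = run_protective_screen(m)
        assert {r.variant_id for r in recurrent} == {
            v for v in m.variant_ids if v.startswith("ex")
        }
        assert report.n_recurrent == 12

    def test_maf_before_exclusive_drops_rare_exclusives(self):
        from acemod.synth_cohort import generate_genotype_matrix

        m = generate_genotype_matrix(
            n_high=15, n_low=44, n_background_variants=80,
            planted_exclusive=12, missing_rate=0.0, seed=6,
        )
        # most planted variants (3-5 carriers of 59) fall below 5% MAF and
        # vanish when the MAF filter precedes the exclusivity screen
        _, recurrent, _ = run_protective_screen(m, maf_before_exclusive=True)
        planted = {v for v in m.variant_ids if v.startswith("ex")}
        assert {r.variant_id for r in recurrent} < planted
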