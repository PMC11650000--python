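"""Statistical battery: t-tests, chi-square, Bonferroni, normality checks.

Oracle strategy: t and chi-square statistics are re-derived from the
textbook formulas on randomly generated small instances and must agree to
1e-10 with the package's results.
"""

import math

import numpy as np
import pytest

import alphaslow as al
from alphaslow.stats import normality


def _student_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def _paired_t_oracle(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    return d.mean() / (d.std(ddof=1) / math.sqrt(d.size))


def _chi2_oracle(tab):
    tab = np.asarray(tab, float)
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    return float(((tab - expected) ** 2 / expected).sum())


class TestUnpairedT:
    def test_identical_groups(self):
        res = al.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_shifted_groups_match_formula(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        res = al.unpaired_t(a, b)
        assert res.statistic == pytest.approx(_student_t_oracle(a, b), abs=1e-10)
        assert res.df == 4.0

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1.0, size=9)
        r1, r2 = al.unpaired_t(a, b), al.unpaired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_random_instances_match_formula_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(rng.normal(), 1 + rng.random(), size=na)
            b = rng.normal(rng.normal(), 1 + rng.random(), size=nb)
            res = al.unpaired_t(a, b)
            assert abs(res.statistic - _student_t_oracle(a, b)) < 1e-10

    def test_cohens_d_sign_matches_statistic(self):
        res = al.unpaired_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert res.statistic > 0 and res.effect_size > 0

    def test_degenerate_zero_variance(self):
        res = al.unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0 and res.warning == "zero_variance"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            al.unpaired_t([1.0], [1.0, 2.0])

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.1, size=20)
        b = rng.normal(0.5, 3.0, size=5)
        student = al.unpaired_t(a, b, variant="student")
        welch = al.unpaired_t(a, b, variant="welch")
        assert student.df != welch.df


class TestPairedT:
    def test_identical_pairs(self):
        res = al.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.warning == "zero_variance"

    def test_constant_shift_degenerate(self):
        res = al.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.p_value == 0.0 and res.warning == "zero_variance"

    def test_five_pair_formula_oracle(self):
        x = [1.2, 2.3, 3.1, 4.0, 5.5]
        y = [1.0, 2.9, 2.5, 4.4, 4.9]
        res = al.paired_t(x, y)
        assert res.statistic == pytest.approx(_paired_t_oracle(x, y), abs=1e-10)
        assert res.df == 4.0

    def test_random_instances_match_formula_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            n = int(rng.integers(2, 15))
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 0.7, size=n)
            res = al.paired_t(x, y)
            assert abs(res.statistic - _paired_t_oracle(x, y)) < 1e-10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            al.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_eeg_sex_table(self):
        """EEG cohort sex table: 11/6 male/female controls vs 9/13 patients."""
        res = al.chi_square_2x2([[11, 9], [6, 13]])
        assert round(res.statistic, 2) == 2.17
        assert res.df == 1.0

    def test_meg_sex_table(self):
        """MEG cohort sex table: 16/30 vs 12/12."""
        res = al.chi_square_2x2([[16, 12], [30, 12]])
        assert round(res.statistic, 2) == 1.52

    def test_proportional_table_is_independent(self):
        res = al.chi_square_2x2([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_random_instances_match_formula_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(1000):
            tab = rng.integers(1, 50, size=(2, 2))
            res = al.chi_square_2x2(tab)
            assert abs(res.statistic - _chi2_oracle(tab)) < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            al.chi_square_2x2([[0, 0], [5, 10]])


class TestBonferroni:
    def test_basic_adjustment(self):
        assert al.bonferroni([0.01, 0.04], m=2) == [0.02, 0.08]

    def test_m_one_is_identity(self):
        assert al.bonferroni([0.37], m=1) == [0.37]

    def test_capped_at_one(self):
        assert al.bonferroni([0.2, 0.5, 0.9], m=34) == [1.0, 1.0, 1.0]

    def test_never_decreases_p(self):
        rng = np.random.default_rng(1)
        ps = rng.random(20).tolist()
        adj = al.bonferroni(ps)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            al.bonferroni([0.1, 0.2, 0.3], m=2)


class TestNormality:
    @pytest.mark.parametrize("test", ["lilliefors", "anderson_darling"])
    def test_type_one_error_under_null(self, test):
        """Normal samples are rarely rejected (>=90/100 seeds accept)."""
        accept = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(200)
            res = normality(x, test=test, replicates=2000)
            accept += res.p_value > 0.05
        assert accept >= 90

    @pytest.mark.parametrize("test", ["lilliefors", "anderson_darling"])
    def test_power_against_exponential(self, test):
        """Heavy-skew samples are nearly always rejected (>=95/100 seeds)."""
        reject = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=200)
            res = normality(x, test=test, replicates=2000)
            reject += res.p_value < 0.05
        assert reject >= 95

    @pytest.mark.parametrize("test", ["lilliefors", "anderson_darling"])
    def test_location_scale_invariance(self, test):
        x = np.random.default_rng(5).standard_normal(100)
        r1 = normality(x, test=test, replicates=500)
        r2 = normality(3.0 + 2.5 * x, test=test, replicates=500)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_lilliefors_agrees_with_statsmodels_statistic(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        x = np.random.default_rng(9).standard_normal(150)
        stat_sm, _ = sm_lilliefors(x, dist="norm")
        res = normality(x, test="lilliefors", replicates=500)
        assert res.statistic == pytest.approx(stat_sm, abs=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality([1.0] * 5)


class TestCohortComparison:
    def test_hemisphere_level_on_synthetic_cohort(self, small_table):
        results = al.cohort_comparison(small_table, "hemisphere")
        assert len(results) == 2
        for r in results:
            assert r.m_corrections == 2
            assert r.p_adjusted >= r.p_value
            assert r.statistic > 0  # patients slower than controls

    def test_region_paired_level(self, small_table):
        results = al.cohort_comparison(small_table, "region_paired")
        assert len(results) == 2
        for r in results:
            assert r.n_per_group == (34,)
            assert r.df == 33.0

    def test_region_unpaired_families_of_34(self, small_table):
        results = al.cohort_comparison(small_table, "region_unpaired")
        assert len(results) == 68
        assert all(r.m_corrections == 34 for r in results)

    def test_single_class_table_rejected(self, small_table):
        import pandas as pd

        from alphaslow.ratio import AlphaRatioTable

        ctl = small_table.group_mask("control")
        tbl = AlphaRatioTable(
            values=small_table.values[ctl],
            subjects=small_table.subjects[ctl].reset_index(drop=True),
            regions=small_table.regions,
        )
        with pytest.raises(ValueError):
            al.cohort_comparison(tbl)


def test_unpaired_t_p_value_calibration():
    """Empirical type-I rate at alpha=0.05 lies in [0.03, 0.07] under the null."""
    rng = np.random.default_rng(2024)
    rejections = 0
    reps = 2000
    for _ in range(reps):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        if al.unpaired_t(a, b).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07
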