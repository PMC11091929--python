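"""Tests for the cohort statistics layer.

Each procedure is checked against closed forms evaluated by hand and
against independent implementations (scipy/statsmodels) on random draws.
"""

import numpy as np
import pytest
from scipy import stats as sps

from oscistate.stats import (
    age_correlation,
    anova_with_posthoc,
    bonferroni,
    chi_square_contingency,
    chi_square_gof,
    demographics_tests,
    homogeneity_gate,
    one_way_anova,
    paired_t,
    standardized_regression,
    tamhane_t2,
    tukey_hsd,
)
from oscistate.synthetic import table1_fixture


class TestChiSquare:
    def test_gof_closed_form(self):
        chi2, df, _ = chi_square_gof([10, 20])
        assert chi2 == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert df == 1

    def test_gof_handedness_counts(self):
        chi2, df, p = chi_square_gof([126, 14])
        assert chi2 == pytest.approx(89.6, abs=1e-9)
        assert p < 0.001
        chi2, _, p = chi_square_gof([75, 75])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_gof_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            obs = rng.integers(1, 50, size=rng.integers(2, 6))
            chi2, df, p = chi_square_gof(obs)
            ref = sps.chisquare(obs)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_gof_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="zero expected"):
            chi_square_gof([5, 5], [1.0, 0.0])

    def test_contingency_diagonal(self):
        chi2, df, _ = chi_square_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_contingency_proportional_rows_independent(self):
        chi2, _, p = chi_square_contingency([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_contingency_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_contingency([[0, 0], [3, 4]])

    def test_cohort_sex_table_value(self):
        table = table1_fixture()
        chi2, df, p = chi_square_contingency(table[["female", "male"]].to_numpy())
        assert df == 4
        assert chi2 == pytest.approx(1.60, abs=0.01)


class TestAnova:
    def test_hand_decomposition(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert (res.df1, res.df2) == (1, 4)

    def test_identical_groups_give_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10), 0.5 + rng.standard_normal(12)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy_on_random_draws(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            groups = [rng.standard_normal(rng.integers(3, 12)) for _ in range(4)]
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)


class TestHomogeneityGate:
    def test_equal_spreads_choose_tukey(self):
        method, _ = homogeneity_gate([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert method == "Tukey"

    def test_gross_heterogeneity_chooses_tamhane(self):
        rng = np.random.default_rng(3)
        groups = [rng.standard_normal(50) for _ in range(4)]
        groups.append(100.0 * rng.standard_normal(50))
        method, p = homogeneity_gate(groups)
        assert method == "TamhaneT2"
        assert p < 1e-6

    def test_zero_alpha_always_tukey(self):
        rng = np.random.default_rng(4)
        groups = [rng.standard_normal(20), 50 * rng.standard_normal(20)]
        method, _ = homogeneity_gate(groups, alpha_homog=0.0)
        assert method == "Tukey"

    def test_gate_consistency_with_attached_posthoc(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            scale = 30.0 if i % 2 else 1.0
            groups = [
                rng.standard_normal(15),
                rng.standard_normal(15),
                scale * rng.standard_normal(15),
            ]
            res = anova_with_posthoc(groups)
            gate, _ = homogeneity_gate(groups)
            assert res.posthoc_method == gate
            assert len(res.pairwise) == 3


class TestTukey:
    def test_identical_groups(self):
        out = tukey_hsd([[1, 2, 3], [1, 2, 3]])
        assert out[0].statistic == 0.0
        assert out[0].p_raw == pytest.approx(1.0)

    def test_symmetry_of_pairs(self):
        rng = np.random.default_rng(6)
        groups = [rng.standard_normal(8) for _ in range(3)]
        out = {(c.group_i, c.group_j): c for c in tukey_hsd(groups)}
        assert set(out) == {(0, 1), (0, 2), (1, 2)}

    def test_matches_scipy_tukey_hsd(self):
        # independent studentized-range implementation as oracle
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [
                rng.standard_normal(5) + off for off in (0.0, 0.8, 1.6)
            ]
            mine = tukey_hsd(groups)
            ref = sps.tukey_hsd(*groups)
            for c in mine:
                assert c.p_raw == pytest.approx(
                    ref.pvalue[c.group_i, c.group_j], abs=1e-8
                )


class TestTamhane:
    def test_frozen_welch_example(self):
        # {1,2,3} vs {4,5,6} among three groups: t=-3.674, Welch df=4,
        # p_raw~0.0214, Sidak-adjusted over m=3 pairs ~0.0629
        out = tamhane_t2([[1, 2, 3], [4, 5, 6], [0, 1, 2]])
        c01 = next(c for c in out if (c.group_i, c.group_j) == (0, 1))
        assert abs(c01.statistic) == pytest.approx(3.674, abs=1e-3)
        assert c01.p_raw == pytest.approx(0.0214, abs=2e-4)
        assert c01.p_adjusted == pytest.approx(1 - (1 - c01.p_raw) ** 3, rel=1e-12)
        assert c01.p_adjusted == pytest.approx(0.0629, abs=1e-3)

    def test_identical_groups(self):
        out = tamhane_t2([[1.0, 2.0], [1.0, 2.0]])
        assert out[0].statistic == 0.0
        assert out[0].p_adjusted == pytest.approx(1.0)

    def test_adjustment_monotonicity(self):
        rng = np.random.default_rng(8)
        groups = [rng.standard_normal(6) + off for off in (0, 0.5, 1.0, 1.5)]
        for c in tamhane_t2(groups):
            assert c.p_adjusted >= c.p_raw - 1e-15


class TestCorrelation:
    def test_exact_linear(self):
        res = age_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_closed_form_half(self):
        res = age_correlation([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert age_correlation(x, y).r == pytest.approx(-age_correlation(x, -y).r)

    def test_r_squared_identity_and_textbook_formula(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            x = rng.standard_normal(12)
            y = 0.3 * x + rng.standard_normal(12)
            res = age_correlation(x, y)
            r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert res.r == pytest.approx(r_hand, rel=1e-10)
            assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)
            t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_correlation([1, 1, 1], [1, 2, 3])


class TestBonferroniAndPairedT:
    def test_bonferroni_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01], 5), [0.05])
        np.testing.assert_allclose(bonferroni([0.3], 4), [1.0])
        np.testing.assert_allclose(bonferroni([0.2, 0.04], 2), [0.4, 0.08])

    def test_bonferroni_family_too_small_rejected(self):
        with pytest.raises(ValueError, match="family size"):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_paired_t_identical_inputs(self):
        t, df, p = paired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_paired_t_closed_form(self):
        t, df, p = paired_t([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert df == 2

    def test_paired_t_antisymmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        t1, _, p1 = paired_t(x, y)
        t2, _, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        ref = sps.ttest_rel(x, y)
        assert t1 == pytest.approx(ref.statistic, rel=1e-12)
        assert p1 == pytest.approx(ref.pvalue, rel=1e-10)

    def test_paired_t_constant_nonzero_difference_overflows(self):
        with pytest.raises(FloatingPointError, match="overflow"):
            paired_t([2, 3, 4], [1, 2, 3])


class TestStandardizedRegression:
    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(40)
        y = 0.6 * x + rng.standard_normal(40)
        res = standardized_regression(y, x)
        assert res.betas[0] == pytest.approx(age_correlation(x, y).r, abs=1e-9)

    def test_orthogonal_predictors_keep_marginal_correlations(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        a = (a - a.mean()) / a.std(ddof=1)
        b -= b @ a / (a @ a) * a  # exact orthogonalization
        b = (b - b.mean()) / b.std(ddof=1)
        y = 0.5 * a - 0.3 * b + 0.1 * rng.standard_normal(200)
        res = standardized_regression(y, np.column_stack([a, b]))
        r_a = age_correlation(a, y).r
        r_b = age_correlation(b, y).r
        # with exactly orthogonal standardized predictors, betas are the
        # marginal correlations (normal-equations closed form)
        assert res.betas[0] == pytest.approx(r_a, abs=1e-6)
        assert res.betas[1] == pytest.approx(r_b, abs=1e-6)

    def test_centering_invariance(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((30, 3))
        y = X @ [0.2, -0.4, 0.1] + rng.standard_normal(30)
        res1 = standardized_regression(y, X)
        res2 = standardized_regression(y, X + np.array([5.0, -2.0, 100.0]))
        np.testing.assert_allclose(res1.betas, res2.betas, atol=1e-10)

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(20)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(ValueError, match="collinear"):
            standardized_regression(rng.standard_normal(20), X)


class TestDemographics:
    def test_battery_matches_printed_statistics(self):
        out = demographics_tests(table1_fixture())
        printed = {
            "sex_gof_YA": 1.20, "sex_gof_EMA": 0.17, "sex_gof_LMA": 0.10,
            "sex_gof_YS": 0.0, "sex_gof_EA": 0.13,
            "handedness_gof_YA": 45.14, "handedness_gof_EMA": 89.6,
            "handedness_gof_LMA": 109.22, "handedness_gof_YS": 98.26,
            "handedness_gof_EA": 96.86,
            "sex_contingency": 1.60, "handedness_contingency": 3.45,
        }
        for key, value in printed.items():
            assert out[key]["chi2"] == pytest.approx(value, abs=0.01), key
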