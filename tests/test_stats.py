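import numpy as np
import pandas as pd
import pytest
import scipy.stats

import cordmeth as cm
from cordmeth.stats import GLMSpec


def brute_force_u(x, y):
    """Independent oracle: direct pair enumeration with half-credit ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_complete_separation(self):
        assert cm.mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_single_tie(self):
        assert cm.mann_whitney_u([1.0], [1.0]).statistic == 0.5

    def test_interleaved_pairs(self):
        res = cm.mann_whitney_u([1, 3], [2, 4])
        assert res.statistic == brute_force_u([1, 3], [2, 4]) == 1.0

    def test_u_statistics_sum_to_n1_n2(self):
        rng = np.random.default_rng(3)
        x, y = rng.integers(0, 5, 6), rng.integers(0, 5, 7)
        uxy = cm.mann_whitney_u(x, y).statistic
        uyx = cm.mann_whitney_u(y, x).statistic
        assert uxy + uyx == pytest.approx(len(x) * len(y))

    def test_matches_brute_force_enumeration_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(1, 9, 2)
            x = rng.integers(0, 4, n1).astype(float)  # heavy ties
            y = rng.integers(0, 4, n2).astype(float)
            assert cm.mann_whitney_u(x, y).statistic == pytest.approx(
                brute_force_u(x, y)
            )

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            cm.mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_independence_gives_zero(self):
        assert cm.pearson_chi_square([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_hand_pearson_formula(self):
        res = cm.pearson_chi_square([[1, 2], [3, 4]])
        expected = np.array([1.2, 1.8, 2.8, 4.2])
        observed = np.array([1, 2, 3, 4])
        assert res.statistic == pytest.approx(((observed - expected) ** 2 / expected).sum())
        assert res.df == 1

    def test_invariant_to_transpose_and_permutation(self):
        table = np.array([[5, 9, 2], [7, 1, 6]])
        base = cm.pearson_chi_square(table).statistic
        assert cm.pearson_chi_square(table.T).statistic == pytest.approx(base)
        assert cm.pearson_chi_square(table[:, [2, 0, 1]]).statistic == pytest.approx(base)
        assert cm.pearson_chi_square(table[[1, 0]]).statistic == pytest.approx(base)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            cm.pearson_chi_square([[0, 0], [3, 4]])

    def test_yates_correction_available_but_not_default(self):
        table = [[16, 19], [24, 23]]
        assert cm.pearson_chi_square(table, correction=True).statistic < \
            cm.pearson_chi_square(table).statistic


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert cm.spearman_rho(x, [2, 3, 8, 9]).statistic == pytest.approx(1.0)
        assert cm.spearman_rho(x, [9, 8, 3, 2]).statistic == pytest.approx(-1.0)

    def test_matches_midrank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert cm.spearman_rho(x, y).statistic == pytest.approx(oracle)

    def test_invariant_under_strictly_increasing_transforms(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=25), rng.normal(size=25)
        base = cm.spearman_rho(x, y).statistic
        assert cm.spearman_rho(np.exp(x), y ** 3 + 2 * y).statistic == pytest.approx(base)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            cm.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cm.spearman_rho([1.0, 2.0], [1.0, 2.0])


class TestInverseGaussianGLM:
    def test_exactly_linear_response_recovered(self):
        x = np.linspace(0, 5, 40)
        design = pd.DataFrame({"x": x})
        response = pd.Series(2.0 + 0.5 * x)
        fit = cm.fit_invgauss_glm(design, response,
                                  GLMSpec("y", ["x"], response_shift=10.0))
        assert fit.coefficients["x"] == pytest.approx(0.5, abs=1e-8)
        assert fit.coefficients["const"] == pytest.approx(12.0, abs=1e-8)
        # zero-residual fixed point: deviance collapses to numerical zero
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_fits_sample_mean(self):
        rng = np.random.default_rng(0)
        response = pd.Series(rng.uniform(-1, 1, 50))
        fit = cm.fit_invgauss_glm(pd.DataFrame(index=response.index), response,
                                  GLMSpec("y", [], response_shift=10.0))
        assert fit.coefficients["const"] == pytest.approx(response.mean() + 10.0, abs=1e-8)

    def test_parameter_recovery_over_replicates(self):
        """mu = 12 + 0.8 x with inverse-Gaussian noise; mean estimates over
        replicates land within 2% of truth."""
        rng = np.random.default_rng(777)
        slopes, intercepts = [], []
        for _ in range(50):
            x = rng.uniform(0, 5, 2000)
            mu, lam = 12 + 0.8 * x, 500.0
            y = scipy.stats.invgauss.rvs(mu / lam, scale=lam, random_state=rng)
            fit = cm.fit_invgauss_glm(
                pd.DataFrame({"x": x}), pd.Series(y),
                GLMSpec("y", ["x"], response_shift=0.0),
            )
            slopes.append(fit.coefficients["x"])
            intercepts.append(fit.coefficients["const"])
        assert np.mean(slopes) == pytest.approx(0.8, rel=0.02)
        assert np.mean(intercepts) == pytest.approx(12.0, rel=0.02)

    def test_nested_model_deviance_ordering(self):
        rng = np.random.default_rng(5)
        design = pd.DataFrame({"x": rng.uniform(0, 2, 60), "z": rng.normal(size=60)})
        response = pd.Series(1.0 + design["x"] + rng.normal(0, 0.3, 60))
        small = cm.fit_invgauss_glm(design, response, GLMSpec("y", ["x"], 10.0))
        big = cm.fit_invgauss_glm(design, response, GLMSpec("y", ["x", "z"], 10.0))
        assert big.deviance <= small.deviance + 1e-10
        assert small.deviance <= small.null_deviance
        assert small.dispersion > 0
        assert small.omnibus_chi2 >= 0

    def test_nonpositive_shifted_response_errors(self):
        design = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="response_shift"):
            cm.fit_invgauss_glm(design, pd.Series([-11.0, 0.0, 1.0]),
                                GLMSpec("y", ["x"], response_shift=10.0))

    def test_rank_deficient_design_errors(self):
        design = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        design["x2"] = 2 * design["x"]
        with pytest.raises(ValueError, match="rank"):
            cm.fit_invgauss_glm(design, pd.Series([1.0, 2.0, 3.0, 4.0]),
                                GLMSpec("y", ["x", "x2"], 10.0))


class TestGroupComparisons:
    def test_table_layout_continuous_and_categorical(self):
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame(
            {
                "group": ["e"] * 20 + ["c"] * 25,
                "age": rng.normal(30, 3, 45),
                "flag": rng.integers(0, 2, 45),
            }
        )
        table = cm.run_group_comparisons(
            cohort, {"age": "continuous", "flag": "categorical"}
        )
        assert list(table["variable"]) == ["age", "flag"]
        assert list(table["statistic_name"]) == ["U", "chi_square"]
        assert set(table.columns) >= {"e_summary", "c_summary", "statistic", "p_value"}

    def test_constant_variable_skipped(self):
        cohort = pd.DataFrame({"group": ["e", "e", "c", "c"], "v": [1.0] * 4})
        table = cm.run_group_comparisons(cohort, {"v": "continuous"})
        assert table.empty

    def test_sex_counts_reproduce_printed_chi_square(self):
        cohort = pd.DataFrame(
            {
                "group": ["PCE"] * 35 + ["control"] * 47,
                "sex_male": [1] * 16 + [0] * 19 + [1] * 24 + [0] * 23,
            }
        )
        table = cm.run_group_comparisons(cohort, {"sex_male": "categorical"})
        assert table.loc[0, "statistic"] == pytest.approx(0.230, abs=5e-4)
        assert table.loc[0, "p_value"] == pytest.approx(0.632, abs=5e-4)

    def test_non_binary_group_errors(self):
        cohort = pd.DataFrame({"group": ["a", "b", "c"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            cm.run_group_comparisons(cohort, {"v": "continuous"})
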