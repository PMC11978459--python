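"""Covariate models: OLS, stepwise reduction, partial r2, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from muscleshape import (fit_glm, backward_stepwise, partial_r2,
                         compare_groups, effect_plot_data, DEFAULT_TERMS,
                         validate_covariates)
from muscleshape.shape_stats import fit_ols

from conftest import make_covariates


class TestValidateCovariates:
    def test_accepts_and_normalizes(self, covariates):
        df = validate_covariates(covariates)
        assert "log_mass" in df.columns
        np.testing.assert_allclose(df["log_mass"], np.log(df["mass"]))
        assert list(df["age_group"].cat.categories) == ["young", "older"]

    def test_rejects_bad_labels(self, covariates):
        bad = covariates.copy()
        bad.loc[0, "sex"] = "unknown"
        with pytest.raises(ValueError, match="sex"):
            validate_covariates(bad)

    def test_rejects_nonpositive(self, covariates):
        bad = covariates.copy()
        bad.loc[0, "volume"] = -1.0
        with pytest.raises(ValueError, match="volume"):
            validate_covariates(bad)

    def test_rejects_duplicate_ids(self, covariates):
        bad = covariates.copy()
        bad.loc[1, "specimen_id"] = bad.loc[0, "specimen_id"]
        with pytest.raises(ValueError, match="unique"):
            validate_covariates(bad)


class TestFitGlm:
    def test_zero_response_handled(self, covariates):
        fit = fit_glm(np.zeros(len(covariates)), covariates)
        assert fit.r_squared == 0.0
        assert np.allclose(fit.coefficients["coef"], 0.0, atol=1e-12)

    def test_slope_recovery(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = 3.0 * df["x"] + 1e-4 * rng.normal(size=200)
        fit = fit_ols(df, "y", ["x"])
        assert fit.coefficients.loc["x", "coef"] == pytest.approx(3.0,
                                                                  abs=1e-3)

    def test_fitted_plus_residuals_reconstruct(self, covariates):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(covariates))
        fit = fit_glm(y, covariates)
        res = fit.sm_result
        np.testing.assert_allclose(res.fittedvalues + res.resid, y,
                                   atol=1e-10)

    def test_residual_df(self, covariates):
        fit = fit_glm(np.arange(len(covariates), dtype=float), covariates)
        n_coef = len(fit.coefficients)
        assert fit.residual_df == len(covariates) - n_coef

    def test_scores_by_id_inner_join(self, covariates):
        rng = np.random.default_rng(2)
        ids = covariates["specimen_id"].tolist()[:-2]   # drop two
        scores = {i: float(v) for i, v in zip(ids, rng.normal(size=len(ids)))}
        fit = fit_glm(scores, covariates, ["height"])
        assert len(fit.data) == len(ids)

    def test_rank_deficiency_names_terms(self, covariates):
        df = covariates.copy()
        df["height2"] = df["height"]
        rng = np.random.default_rng(3)
        df["score"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(df, "score", ["height", "height2"])


class TestBackwardStepwise:
    @staticmethod
    def exhaustive_aic(df, terms, response="y"):
        best = None
        for r in range(len(terms) + 1):
            for sub in itertools.combinations(terms, r):
                f = fit_ols(df, response, list(sub))
                if best is None or f.aic < best.aic - 1e-10:
                    best = f
        return best

    def test_keeps_only_signal_term(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": rng.normal(size=50),
                           "x2": rng.normal(size=50)})
        df["y"] = 2.0 * df["x1"] + 0.01 * rng.normal(size=50)
        red = backward_stepwise(fit_ols(df, "y", ["x1", "x2"]))
        assert red.terms == ["x1"]

    def test_intercept_only_truth(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({f"x{i}": rng.normal(size=60) for i in range(1, 4)})
        df["y"] = rng.normal(size=60)
        red = backward_stepwise(fit_ols(df, "y", ["x1", "x2", "x3"]))
        oracle = self.exhaustive_aic(df, ["x1", "x2", "x3"])
        assert sorted(red.terms) == sorted(oracle.terms)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 5)})
        df["y"] = (2.0 * df["x1"] + 0.8 * df["x2"]
                   + rng.normal(0, 1, n))
        terms = ["x1", "x2", "x3", "x4"]
        greedy = backward_stepwise(fit_ols(df, "y", terms))
        oracle = self.exhaustive_aic(df, terms)
        assert sorted(greedy.terms) == sorted(oracle.terms)

    def test_marginality_protects_main_effects(self, covariates):
        rng = np.random.default_rng(5)
        df = validate_covariates(covariates)
        # strong interaction, weak main effects
        z = ((df["age_group"] == "older").astype(float)
             * (df["sex"] == "male").astype(float))
        y = 3.0 * z.to_numpy() + 0.3 * rng.normal(size=len(df))
        fit = fit_glm(y, covariates,
                      ["age_group", "sex", "age_group:sex"])
        red = backward_stepwise(fit, criterion="alpha")
        assert "age_group:sex" in red.terms
        assert "age_group" in red.terms and "sex" in red.terms

    def test_alpha_mode_drops_nonsignificant(self, covariates):
        rng = np.random.default_rng(6)
        y = rng.normal(size=len(covariates))
        red = backward_stepwise(fit_glm(y, covariates), criterion="alpha")
        for t in red.terms:
            assert red.term_pvalue(t) <= 0.05 or ":" in "".join(red.terms)

    def test_invalid_criterion(self, covariates):
        fit = fit_glm(np.arange(len(covariates), dtype=float), covariates)
        with pytest.raises(ValueError):
            backward_stepwise(fit, criterion="bic")


class TestPartialR2:
    def test_zero_t(self):
        assert partial_r2(0.0, 10) == 0.0

    def test_hand_value(self):
        assert partial_r2(2.0, 16) == pytest.approx(0.2)

    def test_monotone_to_one(self):
        vals = [partial_r2(t, 16) for t in (1, 2, 5, 20, 1000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.999

    def test_matches_rss_ratio_definition(self):
        """t^2/(t^2+df) equals the RSS-based partial r2 on a fitted model."""
        rng = np.random.default_rng(7)
        n = 40
        df = pd.DataFrame({"x1": rng.normal(size=n),
                           "x2": rng.normal(size=n)})
        df["y"] = 1.5 * df["x1"] + 0.7 * df["x2"] + rng.normal(0, 1, n)
        full = fit_ols(df, "y", ["x1", "x2"])
        reduced = fit_ols(df, "y", ["x2"])
        rss_full = float(np.sum(full.sm_result.resid ** 2))
        rss_red = float(np.sum(reduced.sm_result.resid ** 2))
        expected = (rss_red - rss_full) / rss_red
        assert full.partial_r2["x1"] == pytest.approx(expected, abs=1e-12)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            partial_r2(1.0, 0)


class TestCompareGroups:
    def test_separated_normal_samples(self):
        res = compare_groups([1, 2, 3, 4, 5], [11, 12, 13, 14, 15])
        assert res.test_used == "welch_t"
        assert res.pvalue < 0.001

    def test_identical_distributions_sane_p(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(size=20), rng.normal(size=20))
        assert 0.0 < res.pvalue <= 1.0

    def test_skewed_samples_use_mann_whitney(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 1.5, 30))
        y = np.exp(rng.normal(0.5, 1.5, 30))
        res = compare_groups(x, y)
        assert res.test_used == "mann_whitney"

    def test_degenerate_zero_variance(self):
        res = compare_groups([1.0] * 5, [1.0] * 5)
        assert res.test_used == "skipped"
        assert res.mean_difference == 0.0

    def test_small_samples_raise(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEffectPlotData:
    def test_single_covariate_reconstructs_response(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 1.0 + 2.0 * df["x"] + rng.normal(0, 0.5, 50)
        fit = fit_ols(df, "y", ["x"])
        data = effect_plot_data(fit, "x")
        intercept = fit.coefficients.loc["Intercept", "coef"]
        np.testing.assert_allclose(data.table["partial_residual"],
                                   df["y"] - intercept, atol=1e-10)

    def test_partial_residual_slope_equals_coefficient(self, covariates):
        rng = np.random.default_rng(3)
        y = (0.02 * covariates["height"].to_numpy()
             + rng.normal(0, 0.5, len(covariates)))
        fit = fit_glm(y, covariates, ["height", "volume", "sex"])
        data = effect_plot_data(fit, "height")
        x = data.table["x"].to_numpy()
        pr = data.table["partial_residual"].to_numpy()
        slope = np.polyfit(x, pr, 1)[0]
        assert slope == pytest.approx(data.coef, abs=1e-9)

    def test_ci_half_width_large_df_limit(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=5000)})
        df["y"] = df["x"] + rng.normal(size=5000)
        fit = fit_ols(df, "y", ["x"])
        data = effect_plot_data(fit, "x")
        half = (data.coef_ci_high - data.coef_ci_low) / 2.0
        assert half == pytest.approx(1.96 * data.se, rel=1e-3)

    def test_missing_term_raises(self, covariates):
        fit = fit_glm(np.arange(len(covariates), dtype=float), covariates,
                      ["height"])
        with pytest.raises(KeyError):
            effect_plot_data(fit, "volume")


def test_group_shift_recovery_rate():
    """A 1.5 pooled-SD group shift in the scores keeps the group term in
    the reduced model with the right sign in >= 90% of 100 replicates."""
    kept_with_sign = 0
    for rep in range(100):
        rng = np.random.default_rng(700 + rep)
        covariates = make_covariates(rng, n=30)
        older = (covariates["age_group"] == "older").to_numpy(float)
        scores = 1.5 * older + rng.normal(0.0, 1.0, 30)
        reduced = backward_stepwise(fit_glm(scores, covariates))
        if "age_group" in reduced.terms:
            rows = reduced.coefficients[
                reduced.coefficients["term"] == "age_group"]
            kept_with_sign += float(rows["coef"].iloc[0]) > 0
    assert kept_with_sign >= 90
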