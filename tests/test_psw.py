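"""Design matrices, IRLS logistic regression, trimming, weights, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from pretermpsw import psw


def two_by_two_design(n11, n10, n01, n00):
    """Aggregated 2x2 table as a 4-row weighted design (x, y, w)."""
    X = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0]})
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([n11, n10, n01, n00], dtype=float)
    return X, y, w


class TestBuildDesign:
    def test_k_minus_one_dummies(self):
        df = pd.DataFrame({"race_cat": ["white", "black", "brown", "black"]})
        dm = psw.build_design(df, covariates=("race_cat",))
        # reference (white) and absent levels drop; black and brown remain
        assert set(dm.X.columns) == {"race_cat[black]", "race_cat[brown]"}

    def test_reference_row_is_all_zero(self):
        df = pd.DataFrame(
            {"race_cat": ["white", "black"], "age_cat": ["19-34", "<19"]}
        )
        dm = psw.build_design(df, covariates=("race_cat", "age_cat"))
        assert (dm.X.iloc[0] == 0).all()

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"delivery_cat": ["caesarean"] * 4, "age_cat": ["<19", "19-34", "19-34", ">34"]})
        with pytest.warns(UserWarning, match="constant"):
            dm = psw.build_design(df, covariates=("delivery_cat", "age_cat"))
        assert "delivery_cat[caesarean]" in dm.dropped_columns

    def test_unknown_covariate_is_fatal(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            psw.build_design(pd.DataFrame({"a": [1]}), covariates=("nope",))

    def test_complete_case_except_kept_unknowns(self):
        df = pd.DataFrame(
            {
                "race_cat": ["white", "unknown", "black"],
                "sex_cat": ["female", "male", "unknown"],
            }
        )
        dm = psw.build_design(df, covariates=("race_cat", "sex_cat"))
        # row 1 dropped (unknown race); row 2 kept with sex "unknown" indicator
        assert list(dm.X.index) == [0, 2]
        assert dm.n_dropped_rows == 1
        assert "sex_cat[unknown]" in dm.X.columns


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        X, y, w = two_by_two_design(20, 80, 10, 90)
        fit = psw.fit_logistic(X, y, weights=w)
        assert math.exp(fit.params["x"]) == pytest.approx((20 * 90) / (80 * 10), abs=1e-8)

    def test_no_association_gives_unit_or(self):
        X, y, w = two_by_two_design(30, 70, 60, 140)
        fit = psw.fit_logistic(X, y, weights=w)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        y = (rng.random(300) < 0.4).astype(float)
        f0 = psw.fit_logistic(X, y)
        f1 = psw.fit_logistic(X, y, weights=np.ones(300))
        assert np.allclose(f0.params, f1.params, atol=1e-10)
        assert np.allclose(f0.cov, f1.cov, atol=1e-10)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check: coefficients and both covariance flavours
        against a reference GLM implementation on weighted data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 800
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.binomial(1, 0.3, size=n).astype(float)})
        eta = -0.5 + 0.8 * X["a"] - 0.4 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w = rng.uniform(0.5, 3.0, size=n)

        ours = psw.fit_logistic(X, y, weights=w)
        Xs = sm.add_constant(X.to_numpy())
        ref = sm.GLM(y, Xs, family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-7)
        assert np.allclose(
            np.sqrt(np.diag(ours.cov.to_numpy())), ref.bse, atol=1e-7
        )
        # sandwich cross-check at unit weights (the weighted sandwich uses
        # per-unit squared weighted scores, a different weight semantics than
        # the reference implementation's frequency expansion)
        unweighted = psw.fit_logistic(X, y)
        ref_rob = sm.GLM(y, Xs, family=sm.families.Binomial()).fit(cov_type="HC0")
        assert np.allclose(
            np.sqrt(np.diag(unweighted.cov_robust.to_numpy())), ref_rob.bse, rtol=1e-4
        )

    def test_separation_is_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        fit = psw.fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation

    def test_non_convergence_is_flagged(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=200)})
        y = (rng.random(200) < 0.5).astype(float)
        fit = psw.fit_logistic(X, y, max_iter=1, tol=1e-14)
        assert not fit.converged

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError, match="binary"):
            psw.fit_logistic(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0.0, 2.0]))

    def test_rejects_non_positive_weights(self):
        with pytest.raises(ValueError, match="positive"):
            psw.fit_logistic(
                pd.DataFrame({"a": [1.0, 2.0]}), np.array([0.0, 1.0]), weights=[1.0, 0.0]
            )


class TestEstimatePropensity:
    def test_intercept_only_gives_group_share(self, confounded_stacked):
        scores = psw.estimate_propensity(confounded_stacked, ps_covariates=())
        share = confounded_stacked.data["z"].mean()
        assert np.allclose(scores.e, share, atol=1e-8)

    def test_scores_bounded(self, confounded_stacked):
        scores = psw.estimate_propensity(confounded_stacked)
        assert ((scores.e > 0) & (scores.e < 1)).all()

    def test_confounded_scores_separate_periods(self, confounded_stacked):
        """AUC of the score against the period indicator exceeds 0.5."""
        scores = psw.estimate_propensity(confounded_stacked)
        z = confounded_stacked.data.loc[scores.e.index, "z"]
        u = mannwhitneyu(scores.e[z == 1], scores.e[z == 0]).statistic
        auc = u / ((z == 1).sum() * (z == 0).sum())
        assert auc > 0.55


class TestTrimTails:
    def test_fraction_zero_retains_all(self):
        e = pd.Series(np.linspace(0.1, 0.9, 57))
        assert psw.trim_tails(e, 0.0).all()

    def test_identical_scores_all_retained(self):
        e = pd.Series(np.full(100, 0.37))
        assert psw.trim_tails(e, 0.10).all()

    def test_invalid_fraction_is_fatal(self):
        e = pd.Series(np.linspace(0.1, 0.9, 10))
        for bad in (-0.01, 0.5, 0.9):
            with pytest.raises(ValueError):
                psw.trim_tails(e, bad)

    @given(frac=st.floats(min_value=0.0, max_value=0.49), n=st.integers(20, 400))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_fraction(self, frac, n):
        rng = np.random.default_rng(n)
        e = pd.Series(rng.uniform(0.01, 0.99, size=n))
        smaller = psw.trim_tails(e, frac / 2).sum()
        larger = psw.trim_tails(e, frac).sum()
        assert larger <= smaller <= n


class TestComputeWeights:
    @pytest.mark.parametrize(
        "e,z,expected", [(0.5, 1, 2.0), (0.8, 0, 5.0), (0.8, 1, 1.25)]
    )
    def test_ipw_formula(self, e, z, expected):
        w = psw.compute_weights(pd.Series([e]), np.array([z]))
        assert w.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(AssertionError):
            psw.compute_weights(pd.Series([0.0, 0.5]), np.array([1, 0]))


class TestOutcomeModel:
    def test_unit_weights_reproduce_unweighted_fit(self, confounded_stacked):
        data = confounded_stacked.data
        scores = psw.estimate_propensity(confounded_stacked)
        retained = pd.Series(True, index=data.index)
        ones = pd.Series(1.0, index=data.index)
        fit = psw.fit_outcome_model(confounded_stacked, retained, ones)

        design = psw.build_design(data, psw.DEFAULT_OUTCOME_COVARIATES)
        X = design.X.copy()
        X.insert(0, "year", data.loc[X.index, "z"].to_numpy(dtype=float))
        direct = psw.fit_logistic(X, data.loc[X.index, "y"].to_numpy(dtype=float))
        assert np.allclose(fit.fit.params, direct.params, atol=1e-10)

    def test_or_and_ci_consistent(self, confounded_stacked):
        scores = psw.estimate_propensity(confounded_stacked)
        retained = psw.trim_tails(scores.e)
        w = psw.compute_weights(scores.e[retained], confounded_stacked.data.loc[scores.e[retained].index, "z"])
        fit = psw.fit_outcome_model(confounded_stacked, retained, w)
        t = fit.table
        assert (t["or_"] > 0).all()
        assert ((t["ci_low"] < t["or_"]) & (t["or_"] < t["ci_high"])).all()
        assert np.allclose(t["or_"], np.exp(t["coef"]))


class TestDiagnostics:
    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(2)
        e = pd.Series(rng.beta(8, 8, size=2000))
        z = rng.integers(0, 2, size=2000)
        curves = psw.kde_scores(e, z)
        for g in (0, 1):
            area = np.trapezoid(curves[f"density_{g}"], curves["score"])
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_identical_groups_identical_curves(self):
        e = pd.Series(np.tile(np.linspace(0.2, 0.8, 50), 2))
        z = np.repeat([0, 1], 50)
        curves = psw.kde_scores(e, z)
        assert np.allclose(curves["density_0"], curves["density_1"])

    def test_bimodal_scores_show_two_modes(self):
        rng = np.random.default_rng(4)
        e = pd.Series(
            np.concatenate([rng.normal(0.25, 0.03, 500), rng.normal(0.75, 0.03, 500)])
        )
        z = np.zeros(1000, dtype=int)
        d = psw.kde_scores(e, z, bandwidth=0.1)["density_0"].to_numpy()
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        assert interior.sum() >= 2

    def test_degenerate_group_flagged(self):
        e = pd.Series([0.5, 0.5, 0.2, 0.4, 0.6])
        z = np.array([1, 1, 0, 0, 0])
        curves = psw.kde_scores(e, z)
        assert curves.attrs["degenerate"] == [1]
        assert curves["density_1"].isna().all()

    def test_smd_zero_for_identical_groups(self):
        X = pd.DataFrame({"a": np.tile([0.0, 1.0, 2.0], 4)})
        z = np.repeat([0, 1], 6)
        assert psw.balance_smd(X, z)["a"] == pytest.approx(0.0, abs=1e-12)

    def test_smd_formula_unit_shift(self):
        x0 = np.array([-1.0, 1.0] * 50)  # mean 0, variance 1
        X = pd.DataFrame({"a": np.concatenate([x0, x0 + 1.0])})
        z = np.repeat([0, 1], 100)
        assert psw.balance_smd(X, z)["a"] == pytest.approx(1.0, rel=1e-12)

    def test_weighting_improves_balance(self, confounded_stacked):
        scores = psw.estimate_propensity(confounded_stacked)
        z = confounded_stacked.data.loc[scores.e.index, "z"]
        w = psw.compute_weights(scores.e, z)
        report = psw.balance_report(scores.design.X, z, w)
        assert report.attrs["max_abs_smd_weighted"] < report.attrs["max_abs_smd_unweighted"]
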