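"""Proportional-odds model, linear fits, group comparisons and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from msapop.phenotype import (
    ConvergenceError,
    anova_lm,
    fit_linear,
    fit_proportional_odds,
    group_compare,
    pca_scores,
    wald_summary,
)
from msapop.synth import simulate_ordinal

import oracles


def _ordinal_data(rng, n, beta, cutpoints, x_scale=1.0):
    x = rng.normal(scale=x_scale, size=n)
    y = simulate_ordinal(beta * x, np.asarray(cutpoints), rng)
    return y, x


class TestProportionalOdds:
    def test_binary_case_matches_logistic_oracle(self):
        """With K = 2 the cumulative-logit model is plain logistic
        regression: slope and cutpoint match a direct ML logistic fit."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            y, x = _ordinal_data(rng, 300, 0.8, [0.2])
            fit = fit_proportional_odds(y, pd.DataFrame({"x": x}))
            intercept, slope = oracles.logistic_ml_oracle((y == 2).astype(float), x)
            # P(y=2) = expit(x*beta - zeta1)
            assert fit.params[0] == pytest.approx(slope, abs=1e-6)
            assert fit.cutpoints[0] == pytest.approx(-intercept, abs=1e-6)

    def test_no_predictor_balanced_binary_cutpoint_zero(self):
        fit = fit_proportional_odds([1, 1, 2, 2])
        assert fit.cutpoints[0] == pytest.approx(0.0, abs=1e-10)

    def test_parameter_recovery_large_n(self):
        """Simulated beta recovered within 2 SE at n = 5000."""
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.uniform(0, 50, size=n)  # TBT-like scale
        beta = 0.03
        cuts = np.array([-0.5, 0.0, 0.4, 0.8, 1.2, 1.6, 2.0]) + beta * 25
        y = simulate_ordinal(beta * x, cuts, rng)
        fit = fit_proportional_odds(y, pd.DataFrame({"TBT": x}))
        assert fit.converged
        assert abs(fit.params[0] - beta) < 2 * fit.bse[0]

    def test_loglik_monotone_across_iterations(self):
        rng = np.random.default_rng(2)
        y, x = _ordinal_data(rng, 400, 1.2, [-1.0, 0.5, 1.5])
        fit = fit_proportional_odds(y, pd.DataFrame({"x": x}))
        hist = np.array(fit.llf_history)
        assert (np.diff(hist) >= -1e-9).all()

    def test_cutpoints_strictly_increasing_and_aic_identity(self):
        rng = np.random.default_rng(3)
        y, x = _ordinal_data(rng, 500, 0.5, [-1.0, 0.0, 1.0])
        fit = fit_proportional_odds(y, pd.DataFrame({"x": x}))
        assert (np.diff(fit.cutpoints) > 0).all()
        k = len(fit.params) + len(fit.cutpoints)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k, abs=1e-10)

    def test_scale_consistency(self):
        """Rescaling a predictor by c rescales beta and SE by 1/c, leaving
        t, p and AIC unchanged."""
        rng = np.random.default_rng(4)
        y, x = _ordinal_data(rng, 600, 0.6, [-0.5, 0.5])
        f1 = fit_proportional_odds(y, pd.DataFrame({"x": x}))
        c = 10.0
        f2 = fit_proportional_odds(y, pd.DataFrame({"x": x * c}))
        assert f2.params[0] == pytest.approx(f1.params[0] / c, rel=1e-5)
        assert f2.bse[0] == pytest.approx(f1.bse[0] / c, rel=1e-4)
        assert f2.tvalues[0] == pytest.approx(f1.tvalues[0], rel=1e-5)
        assert f2.aic == pytest.approx(f1.aic, abs=1e-6)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(5)
        y, x = _ordinal_data(rng, 400, 0.9, [-1.0, 0.2, 1.4])
        ours = fit_proportional_odds(y, pd.DataFrame({"x": x}))
        sm_fit = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
        assert ours.params[0] == pytest.approx(sm_fit.params[0], abs=1e-4)
        assert ours.llf == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_empty_declared_level_collapsed_with_warning(self):
        y = [1, 1, 2, 2, 4, 4, 4, 1, 2, 4]
        with pytest.warns(UserWarning, match="collapsed"):
            fit = fit_proportional_odds(y, levels=[1, 2, 3, 4])
        assert len(fit.cutpoints) == 2  # three observed categories

    def test_complete_separation_raises_naming_predictor(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.ones(20), 2 * np.ones(20)].astype(int)
        with pytest.raises(ConvergenceError, match="sep"):
            fit_proportional_odds(y, pd.DataFrame({"sep": x}))

    def test_single_category_errors(self):
        with pytest.raises(ValueError, match="two observed categories"):
            fit_proportional_odds([3, 3, 3, 3])


class TestWaldSummary:
    def test_arithmetic_from_printed_style_inputs(self):
        """OR, t and CI arithmetic on coefficient/SE pairs of the magnitude
        monitoring studies print."""
        rng = np.random.default_rng(6)
        y, x = _ordinal_data(rng, 500, 0.5, [-1, 0, 1])
        fit = fit_proportional_odds(y, pd.DataFrame({"x": x}))
        tab = wald_summary(fit)
        row = tab.iloc[0]
        assert row["t_value"] == pytest.approx(row["value"] / row["se"])
        assert row["OR"] == pytest.approx(np.exp(row["value"]))
        assert row["ci_low"] == pytest.approx(np.exp(row["value"] - 1.96 * row["se"]),
                                              rel=1e-3)
        assert tab["AIC"].iloc[0] == pytest.approx(fit.aic)

    def test_zero_beta_gives_unit_or_symmetric_ci(self):
        # direct arithmetic: beta = 0 with any SE
        or_ = np.exp(0.0)
        lo, hi = np.exp(0.0 - 1.96 * 0.2), np.exp(0.0 + 1.96 * 0.2)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)


class TestLinearModels:
    def test_two_points_exact_interpolation(self):
        fit = fit_linear([1.0, 3.0, 5.0], pd.DataFrame({"x": [0.0, 1.0, 2.0]}))
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = rng.normal(size=(30, 3))
            y = X @ [1.0, -2.0, 0.5] + rng.normal(size=30)
            fit = fit_linear(y, pd.DataFrame(X, columns=list("abc")))
            ref = oracles.ols_normal_equations(y, X)
            assert fit.params.to_numpy() == pytest.approx(ref, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        pvals = [
            fit_linear(rng.normal(size=25),
                       pd.DataFrame({"x": rng.normal(size=25)})).f_pvalue
            for _ in range(400)
        ]
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficiency_names_aliased_column(self):
        X = pd.DataFrame(dict(a=[1.0, 2, 3, 4], b=[2.0, 4, 6, 8]))
        with pytest.raises(ValueError, match="aliased"):
            fit_linear([1.0, 2, 3, 4], X)

    def test_one_way_anova_f(self):
        y = [1.0, 1.1, 0.9, 5.0, 5.2, 4.9]
        fit = anova_lm(y, ["a", "a", "a", "b", "b", "b"])
        from scipy import stats

        f_ref, p_ref = stats.f_oneway(y[:3], y[3:])
        assert fit.fvalue == pytest.approx(f_ref)
        assert fit.f_pvalue == pytest.approx(p_ref)
        assert (fit.df_model, fit.df_resid) == (1, 4)


class TestGroupCompare:
    def test_identical_groups_f_zero_shared_letters(self):
        v = [1.0, 2.0, 3.0] * 3
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = group_compare(v, g)
        assert res.statistic == pytest.approx(0.0)
        assert len(set(res.letters.values())) == 1

    def test_mann_whitney_exact_enumeration(self):
        res = group_compare([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3,
                            method="mann_whitney")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)

    def test_mann_whitney_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.permutation(20)[:5].astype(float)
            b = rng.permutation(20)[:6].astype(float) + 0.5  # never ties with a
            res = group_compare(np.r_[a, b], ["a"] * 5 + ["b"] * 6,
                                method="mann_whitney")
            assert res.p_value == pytest.approx(oracles.mann_whitney_exact(a, b))

    def test_tukey_agrees_with_bonferroni_on_separated_groups(self):
        rng = np.random.default_rng(10)
        from scipy import stats

        groups = {
            "low": rng.normal(0, 1, 15),
            "mid": rng.normal(6, 1, 15),
            "high": rng.normal(12, 1, 15),
        }
        v = np.concatenate(list(groups.values()))
        g = np.repeat(list(groups.keys()), 15)
        res = group_compare(v, g)
        names = list(groups)
        m = 3  # number of pairwise tests
        for i in range(3):
            for j in range(i + 1, 3):
                t_p = stats.ttest_ind(groups[names[i]], groups[names[j]]).pvalue
                bonf_sig = t_p * m < 0.05
                row = res.pairwise[
                    (res.pairwise["group1"].isin([names[i], names[j]]))
                    & (res.pairwise["group2"].isin([names[i], names[j]]))
                ].iloc[0]
                assert bool(row["reject"]) == bonf_sig
        assert len(set(res.letters.values())) == 3

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPca:
    def test_collinear_points_single_component(self):
        t = pd.DataFrame(dict(a=[1.0, 2, 3, 4], b=[2.0, 4, 6, 8]))
        res = pca_scores(t, preprocess=None)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(11)
        t = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pca_scores(t, preprocess="standardise")
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(12)
        t = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        res = pca_scores(t, preprocess=None)
        scores_ref, _, pct_ref = oracles.pca_svd_oracle(t.to_numpy())
        assert np.abs(res.percent_variance - pct_ref).max() < 1e-8
        # scores agree up to per-axis sign
        ours = res.scores.to_numpy()
        for k in range(ours.shape[1]):
            assert min(
                np.abs(ours[:, k] - scores_ref[:, k]).max(),
                np.abs(ours[:, k] + scores_ref[:, k]).max(),
            ) < 1e-8

    def test_log_length_normalisation(self):
        rng = np.random.default_rng(13)
        tl = rng.uniform(40, 60, 20)
        t = pd.DataFrame(dict(tl=tl, tb=0.6 * tl * np.exp(rng.normal(0, 0.05, 20)),
                              aw=0.3 * tl))
        with pytest.warns(UserWarning, match="constant"):
            res = pca_scores(t, preprocess="log_length_norm", length_col="tl")
        # aw/tl is exactly constant after normalisation -> dropped
        assert list(res.loadings.index) == ["tb"]

    def test_constant_column_dropped(self):
        t = pd.DataFrame(dict(a=[1.0, 2, 3, 4], b=[5.0, 5, 5, 5]))
        with pytest.warns(UserWarning, match="constant"):
            res = pca_scores(t, preprocess=None)
        assert "b" not in res.loadings.index
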