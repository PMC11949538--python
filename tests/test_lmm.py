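"""Nested-LMM engine: OLS degeneracy, dense-matrix GLS oracle, statsmodels
cross-check, marginal R^2."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ddpgs.lmm import NestedLMM, marginal_r2, marginal_r2_delta


def make_data(n=500, n_sites=8, sigma_site=0.3, sigma_fam=0.5, sigma=1.0,
              beta=(1.0, 0.4), seed=0, fam_size=2):
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(n // fam_size), fam_size)[:n]
    site = fam % n_sites
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    y = (
        X @ np.asarray(beta)
        + sigma_site * rng.standard_normal(n_sites)[site]
        + sigma_fam * rng.standard_normal(fam.max() + 1)[fam]
        + sigma * rng.standard_normal(n)
    )
    return y, X, site.astype(str), np.char.add("f", fam.astype(str))


class TestAgainstOracles:
    def test_reduces_to_ols_without_group_variance(self):
        # singleton families: the family component is then degenerate with the
        # residual, and with many observations per site the fitted site
        # variance is tiny, so GLS must collapse onto OLS
        y, X, site, fam = make_data(
            n=4000, n_sites=8, sigma_site=0.0, sigma_fam=0.0, seed=3, fam_size=1
        )
        fit = NestedLMM(y, X, site, fam).fit()
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ols.params, rtol=1e-4)
        np.testing.assert_allclose(fit.bse, ols.bse, rtol=1e-2)
        assert fit.sigma2_site < 0.05

    def test_exactly_ols_at_zero_variance_ratios(self):
        """At variance ratios fixed to zero the profiled GLS solution is the
        OLS estimator, to machine precision."""
        y, X, site, fam = make_data(n=500, seed=3)
        m = NestedLMM(y, X, site, fam)
        beta, XtViX, _, q, _ = m._profile(0.0, 0.0)
        ols = sm.OLS(m.y, m.X).fit()
        np.testing.assert_allclose(beta, ols.params, rtol=1e-10)
        se = np.sqrt(np.diag(q / (m.n - m.p) * np.linalg.inv(XtViX)))
        np.testing.assert_allclose(se, ols.bse, rtol=1e-10)

    def test_matches_dense_gls_at_fitted_components(self):
        """beta, SE and the profiled residual variance agree with an explicit
        dense-matrix GLS at the fitted variance components."""
        y, X, site, fam = make_data(n=400, seed=5)
        fit = NestedLMM(y, X, site, fam).fit()
        n = len(y)
        Zs = (site[:, None] == np.unique(site)[None, :]).astype(float)
        Zf = (fam[:, None] == np.unique(fam)[None, :]).astype(float)
        V = (
            fit.sigma2 * np.eye(n)
            + fit.sigma2_site * Zs @ Zs.T
            + fit.sigma2_family * Zf @ Zf.T
        )
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        se = np.sqrt(np.diag(np.linalg.inv(XtViX)))
        np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
        np.testing.assert_allclose(fit.bse, se, rtol=1e-8)

    def test_matches_statsmodels_mixedlm_optimum(self):
        """Variance components and REML log-likelihood agree with MixedLM
        (restarted from our optimum, since its default search can stall)."""
        y, X, site, fam = make_data(n=600, n_sites=10, seed=7)
        fit = NestedLMM(y, X, site, fam).fit()
        df = pd.DataFrame({"y": y, "x": X[:, 1], "site": site, "family": fam})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM.from_formula(
                "y ~ x", groups="site", re_formula="1",
                vc_formula={"family": "0 + C(family)"}, data=df,
            )
            res = mod.fit(reml=True)
            res = mod.fit(reml=True, method="lbfgs", start_params=res.params_object)
        assert fit.reml_loglike == pytest.approx(res.llf, abs=1e-4)
        assert fit.sigma2 == pytest.approx(res.scale, rel=1e-3)
        assert fit.sigma2_site == pytest.approx(float(res.cov_re.iloc[0, 0]), rel=2e-2, abs=1e-3)
        assert fit.sigma2_family == pytest.approx(float(res.vcomp[0]), rel=2e-2, abs=1e-3)
        np.testing.assert_allclose(fit.params, res.fe_params.to_numpy(), rtol=1e-4)

    def test_warm_start_equals_cold_start(self):
        y, X, site, fam = make_data(n=500, seed=11)
        cold = NestedLMM(y, X, site, fam).fit()
        warm = NestedLMM(y, X, site, fam).fit(start_theta=cold.theta + 0.2)
        np.testing.assert_allclose(cold.params, warm.params, rtol=1e-6)
        np.testing.assert_allclose(cold.bse, warm.bse, rtol=1e-5)


class TestStructure:
    def test_family_in_two_sites_rejected(self):
        y, X, site, fam = make_data(n=100)
        site = site.copy()
        site[0] = "999"  # first member of f0 moved to another site
        with pytest.raises(ValueError, match="more than one site"):
            NestedLMM(y, X, site, fam)

    def test_row_order_invariance(self):
        y, X, site, fam = make_data(n=300, seed=13)
        fit1 = NestedLMM(y, X, site, fam).fit()
        perm = np.random.default_rng(0).permutation(len(y))
        fit2 = NestedLMM(y[perm], X[perm], site[perm], fam[perm]).fit()
        # summation order inside groups shifts the optimizer path at fp level
        np.testing.assert_allclose(fit1.params, fit2.params, rtol=1e-6)
        np.testing.assert_allclose(fit1.bse, fit2.bse, rtol=1e-6)

    def test_wald_pvalues_and_ci(self):
        y, X, site, fam = make_data(n=2000, beta=(0.0, 0.5), seed=17)
        fit = NestedLMM(y, X, site, fam).fit()
        assert fit.pvalues[1] < 1e-6  # strong true effect
        lo, hi = fit.conf_int()[1]
        assert lo < 0.5 < hi or abs(fit.params[1] - 0.5) < 0.15


class TestMarginalR2:
    def test_delta_matches_ols_r2_difference_without_random_effects(self):
        rng = np.random.default_rng(19)
        n = 3000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.7 * x1 + 0.5 * x2 + rng.standard_normal(n)
        site = np.repeat(np.arange(10), n // 10)
        fam = np.arange(n)  # singleton families
        X_full = np.column_stack([np.ones(n), x1, x2])
        X_red = np.column_stack([np.ones(n), x2])
        full = NestedLMM(y, X_full, site, fam).fit()
        red = NestedLMM(y, X_red, site, fam).fit()
        delta = marginal_r2_delta(full, X_full, red, X_red)
        ols_delta = (
            sm.OLS(y, X_full).fit().rsquared - sm.OLS(y, X_red).fit().rsquared
        )
        assert delta == pytest.approx(ols_delta, abs=0.01)

    def test_zero_coefficient_gives_zero_delta(self):
        y, X, site, fam = make_data(n=600, seed=23)
        full = NestedLMM(y, X, site, fam).fit()
        full.params = np.array([full.params[0], 0.0])  # slope exactly zero
        red = NestedLMM(y, X[:, :1], site, fam).fit()
        # only the intercept contributes to either linear predictor
        assert marginal_r2(full, X) == pytest.approx(0.0, abs=1e-12)
        assert abs(marginal_r2_delta(full, X, red, X[:, :1])) <= 1e-12

    def test_row_mismatch_rejected(self):
        y, X, site, fam = make_data(n=200)
        f1 = NestedLMM(y, X, site, fam).fit()
        f2 = NestedLMM(y[:100], X[:100], site[:100], fam[:100]).fit()
        with pytest.raises(ValueError):
            marginal_r2_delta(f1, X, f2, X[:100])

    def test_known_variance_budget(self):
        """R^2m approaches the analytic fixed/(fixed+random+resid) ratio."""
        rng = np.random.default_rng(29)
        n = 6000
        x = rng.standard_normal(n)
        fam = np.arange(n) // 2
        site = fam % 15
        y = (
            0.6 * x
            + 0.4 * rng.standard_normal(15)[site]
            + 0.5 * rng.standard_normal(fam.max() + 1)[fam]
            + 0.8 * rng.standard_normal(n)
        )
        X = np.column_stack([np.ones(n), x])
        fit = NestedLMM(y, X, site, fam).fit()
        target = 0.36 / (0.36 + 0.16 + 0.25 + 0.64)
        assert marginal_r2(fit, X) == pytest.approx(target, abs=0.05)
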