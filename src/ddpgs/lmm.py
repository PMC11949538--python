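"""Linear mixed model with nested random intercepts: families within sites.

Model
-----
    y = X beta + b_site + b_family + e,
    b_site ~ N(0, sigma2_site), b_family ~ N(0, sigma2_family),
    e ~ N(0, sigma2) i.i.d., families nested within sites.

Fitting is restricted maximum likelihood (REML).  The marginal covariance

    V = sigma2 * (I + g_f Z_f Z_f' + g_s Z_s Z_s')

(with variance ratios g_f = sigma2_family/sigma2, g_s = sigma2_site/sigma2)
is block-diagonal by site, and within a site is a family-block-diagonal
matrix plus a rank-one site term, so V^{-1} M and log|V| have closed forms
via two nested Woodbury identities that cost O(n p) per likelihood
evaluation — no dense matrix is ever formed.  beta and sigma2 are profiled
out; the two variance ratios are optimised on the log scale by Nelder–Mead
from method-of-moments starting values.  The fit is deterministic.

Fixed-effect inference is Wald with the normal reference distribution.
A variance ratio estimated at (numerically) zero is reported as a boundary
fit via ``LMMFit.boundary``; the model remains valid (it degenerates to the
family-only or OLS special case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_RATIO_MIN = -30.0  # exp(-30) ~ 1e-13: effectively a zero variance ratio
_LOG_RATIO_MAX = 10.0


@dataclass
class LMMFit:
    """REML fit of the nested random-intercept model."""

    params: np.ndarray          # fixed-effect estimates, order of X columns
    bse: np.ndarray             # standard errors
    vcov: np.ndarray
    sigma2: float               # residual variance
    sigma2_family: float
    sigma2_site: float
    reml_loglike: float
    n: int
    p: int
    converged: bool
    boundary: bool              # a variance ratio hit its lower bound
    exog_names: list[str]
    theta: np.ndarray = None    # optimised log variance ratios (family, site)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def fixed_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.params


class NestedLMM:
    """REML engine; construct with response, design and grouping factors.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (include the intercept column yourself)
    site, family : (n,) grouping labels; every family must belong to a
        single site.
    """

    def __init__(self, y, X, site, family, exog_names=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(y) != len(X):
            raise ValueError("y and X must have matching first dimension")
        n = len(y)
        site = np.asarray(site)
        family = np.asarray(family)
        if len(site) != n or len(family) != n:
            raise ValueError("site and family must have length n")
        # family labels must be unique across sites
        fam_site = {}
        for s, f in zip(site, family):
            if f in fam_site and fam_site[f] != s:
                raise ValueError(f"family {f!r} appears in more than one site")
            fam_site[f] = s
        order = np.lexsort((family, site))
        self._order = order
        self.y = y[order]
        self.X = X[order]
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need n > p")
        fam_sorted = family[order]
        site_sorted = site[order]
        # run-length starts for families and sites in the sorted arrays
        self._fam_start = np.flatnonzero(
            np.r_[True, (fam_sorted[1:] != fam_sorted[:-1]) | (site_sorted[1:] != site_sorted[:-1])]
        )
        self._site_start = np.flatnonzero(np.r_[True, site_sorted[1:] != site_sorted[:-1]])
        self._fam_sizes = np.diff(np.r_[self._fam_start, self.n]).astype(float)
        # for each family, which site run it belongs to
        self._fam_site = np.searchsorted(self._site_start, self._fam_start, side="right") - 1
        self._site_sizes = np.diff(np.r_[self._site_start, self.n]).astype(float)
        # first family (index into the family arrays) of each site run
        self._site_first_fam = np.flatnonzero(
            np.r_[True, self._fam_site[1:] != self._fam_site[:-1]]
        )
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(self.p)]
        )
        # cross-products reused by every likelihood evaluation: the profiled
        # REML needs only Z'V^{-1}Z, which reduces to family-level sums
        Z = np.column_stack([self.X, self.y])
        self._Z = Z
        self._ZtZ = Z.T @ Z
        self._famZ = np.add.reduceat(Z, self._fam_start, axis=0)  # (F, p+1)

    # ---- core algebra -------------------------------------------------
    def _cross_products(self, g_f: float, g_s: float):
        """Z' V0^{-1} Z and log|V0| (V0 = V / sigma2) from family-level
        sums: two nested Woodbury identities collapse the whole computation
        to O(F p^2) per evaluation."""
        nf = self._fam_sizes
        a = 1.0 / (1.0 + g_f * nf)                     # (W^{-1} 1) within family
        famZ = self._famZ
        ZtWiZ = self._ZtZ - famZ.T @ ((g_f * a)[:, None] * famZ)
        t_site = np.add.reduceat(nf * a, self._site_first_fam)
        uZ = np.add.reduceat(a[:, None] * famZ, self._site_first_fam, axis=0)
        c_s = g_s / (1.0 + g_s * t_site)
        ZtViZ = ZtWiZ - uZ.T @ (c_s[:, None] * uZ)
        logdet = float(np.sum(np.log1p(g_f * nf)) + np.sum(np.log1p(g_s * t_site)))
        return ZtViZ, logdet

    def _profile(self, g_f: float, g_s: float):
        ZtViZ, logdet = self._cross_products(g_f, g_s)
        XtViX = ZtViZ[: self.p, : self.p]
        XtViy = ZtViZ[: self.p, self.p]
        ytViy = ZtViZ[self.p, self.p]
        try:
            cF = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(XtViX, XtViy)
        q = float(ytViy - XtViy @ beta)
        if q <= 0:
            return None
        return beta, XtViX, cF, q, logdet

    def _neg2reml(self, theta: np.ndarray) -> float:
        g_f, g_s = np.exp(np.clip(theta, _LOG_RATIO_MIN, _LOG_RATIO_MAX))
        prof = self._profile(g_f, g_s)
        if prof is None:
            return np.inf
        _, _, cF, q, logdet = prof
        nmp = self.n - self.p
        return logdet + 2.0 * np.log(np.diag(cF)).sum() + nmp * np.log(q / nmp)

    def _mom_start(self) -> np.ndarray:
        """Method-of-moments starting values for the log variance ratios."""
        # OLS residuals (from cached cross-products), then between-group
        # mean squares
        beta = np.linalg.lstsq(
            self._ZtZ[: self.p, : self.p], self._ZtZ[: self.p, self.p], rcond=None
        )[0]
        r = self.y - self.X @ beta
        tot = float(np.var(r)) or 1.0
        fam_means = np.add.reduceat(r, self._fam_start) / self._fam_sizes
        site_sizes = self._site_sizes
        site_means = np.add.reduceat(r, self._site_start) / site_sizes
        v_fam = max(float(np.var(fam_means)) - tot * float(np.mean(1.0 / self._fam_sizes)), 0.0)
        v_site = max(float(np.var(site_means)) - tot * float(np.mean(1.0 / site_sizes)), 0.0)
        v_resid = max(tot - v_fam - v_site, 0.05 * tot)
        g = np.array([v_fam, v_site]) / v_resid
        return np.log(np.maximum(g, 1e-4))

    def fit(self, start_theta=None) -> LMMFit:
        """REML fit.  ``start_theta`` warm-starts the variance-ratio search
        (log scale, e.g. from a nested model on the same rows); the default
        start is method-of-moments."""
        if start_theta is None:
            start = self._mom_start()
            spread = 0.7
        else:
            start = np.asarray(start_theta, dtype=float)
            spread = 0.1
        simplex0 = np.vstack(
            [start, start + np.array([spread, 0.0]), start + np.array([0.0, spread])]
        )
        res = optimize.minimize(
            self._neg2reml,
            start,
            method="Nelder-Mead",
            options={
                "xatol": 1e-6,
                "fatol": 1e-10,
                "maxiter": 1000,
                "initial_simplex": simplex0,
            },
        )
        if not res.success:  # rare: restart once from the found point
            res2 = optimize.minimize(
                self._neg2reml,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 1000},
            )
            if res2.fun <= res.fun:
                res = res2
        theta = np.clip(res.x, _LOG_RATIO_MIN, _LOG_RATIO_MAX)
        g_f, g_s = np.exp(theta)
        prof = self._profile(g_f, g_s)
        if prof is None:
            raise RuntimeError("REML profile degenerate at the optimum; fit failed")
        beta, XtViX, _, q, _ = prof
        nmp = self.n - self.p
        sigma2 = q / nmp
        vcov = sigma2 * np.linalg.inv(XtViX)
        const = nmp * (1 + np.log(2 * np.pi))
        loglike = -0.5 * (res.fun + const)
        boundary = bool(np.any(theta <= _LOG_RATIO_MIN + 1e-6))
        return LMMFit(
            params=beta,
            bse=np.sqrt(np.diag(vcov)),
            vcov=vcov,
            sigma2=float(sigma2),
            sigma2_family=float(g_f * sigma2),
            sigma2_site=float(g_s * sigma2),
            reml_loglike=float(loglike),
            n=self.n,
            p=self.p,
            converged=bool(res.success),
            boundary=boundary,
            exog_names=self.exog_names,
            theta=theta,
        )


def marginal_r2(fit: LMMFit, X: np.ndarray) -> float:
    """Nakagawa–Schielzeth marginal R^2: variance of the fixed-effect linear
    predictor over (fixed + site + family + residual) variance."""
    var_fix = float(np.var(fit.fixed_predictor(X)))
    return var_fix / (var_fix + fit.sigma2_site + fit.sigma2_family + fit.sigma2)


def marginal_r2_delta(
    fit_full: LMMFit, X_full: np.ndarray, fit_reduced: LMMFit, X_reduced: np.ndarray
) -> float:
    """R^2m(full) - R^2m(reduced); both fits must use identical rows."""
    if fit_full.n != fit_reduced.n:
        raise ValueError("full and reduced fits must use identical rows")
    return marginal_r2(fit_full, X_full) - marginal_r2(fit_reduced, X_reduced)
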