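"""Polygenic-score association battery on discounting outcomes.

One linear mixed model per (PGS, outcome) pair — random intercepts for data
collection site and for family within site — adjusted for age, sex, income
and the top ten within-ancestry PCs.  Within each genetic ancestry group
the battery runs 11 predictors x 3 outcomes = 33 tests and controls the
false discovery rate with Benjamini–Hochberg at q = 0.05.  Predictor and
outcome are z-standardised within group before fitting (configurable), so
betas are in SD units.  Each test also reports the Nakagawa–Schielzeth
marginal-R^2 gain of adding the PGS to the covariate-only model fitted on
identical rows.

Usage::

    model = PGSAssociationModel.from_dataframe(df, outcome="log_k",
                                               predictor="pgs_delay_discounting")
    res = model.fit()
    print(res.summary())

or, for the full battery, :func:`run_association_battery`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, NestedLMM, marginal_r2, marginal_r2_delta

OUTCOMES = ("auc", "log_auc", "log_k")
DEFAULT_COVARIATES = ("age", "sex", "income") + tuple(f"PC{i}" for i in range(1, 11))


@dataclass
class ModelSpec:
    """Design of one association model."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    site_col: str = "site_id"
    family_col: str = "family_id"
    standardize: str = "both"  # "both" | "predictor" | "none"

    def __post_init__(self) -> None:
        if self.standardize not in ("both", "predictor", "none"):
            raise ValueError("standardize must be 'both', 'predictor' or 'none'")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant column")
    return (x - np.mean(x)) / sd


class PGSAssociationModel:
    """Nested mixed model for one (PGS, outcome) pair.

    Rows with missing values in any model column are dropped (complete
    case); the count is recorded in ``n_dropped``.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        cols = [spec.outcome, spec.predictor, *spec.covariates, spec.site_col, spec.family_col]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns {missing}")
        sub = data[cols].dropna()
        self.n_dropped = len(data) - len(sub)
        if len(sub) < 50:
            raise ValueError(f"only {len(sub)} complete-case rows; >= 50 required")
        if sub[spec.site_col].nunique() < 2:
            raise ValueError("need >= 2 sites")
        y = sub[spec.outcome].to_numpy(dtype=float)
        x = sub[spec.predictor].to_numpy(dtype=float)
        if spec.standardize in ("both", "predictor"):
            x = _zscore(x)
        if spec.standardize == "both":
            y = _zscore(y)
        C = sub[list(spec.covariates)].to_numpy(dtype=float)
        self.exog_names = ["const", spec.predictor, *spec.covariates]
        self._X_full = np.column_stack([np.ones(len(sub)), x, C])
        self._X_reduced = np.column_stack([np.ones(len(sub)), C])
        self._y = y
        self._site = sub[spec.site_col].to_numpy()
        self._family = sub[spec.family_col].to_numpy()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, predictor: str, **spec_kwargs
    ) -> "PGSAssociationModel":
        return cls(data, ModelSpec(outcome=outcome, predictor=predictor, **spec_kwargs))

    def fit(self) -> "PGSAssociationResults":
        full = NestedLMM(
            self._y, self._X_full, self._site, self._family, exog_names=self.exog_names
        ).fit()
        reduced = NestedLMM(
            self._y, self._X_reduced, self._site, self._family
        ).fit()
        return PGSAssociationResults(self, full, reduced)


class PGSAssociationResults:
    """Results wrapper: estimates, Wald inference, variance components and
    the marginal-R^2 delta attributable to the PGS."""

    def __init__(self, model: PGSAssociationModel, full: LMMFit, reduced: LMMFit):
        self.model = model
        self._full = full
        self._reduced = reduced
        self.params = pd.Series(full.params, index=full.exog_names)
        self.bse = pd.Series(full.bse, index=full.exog_names)
        self.pvalues = pd.Series(full.pvalues, index=full.exog_names)
        self.nobs = full.n

    @property
    def beta(self) -> float:
        return float(self.params[self.model.spec.predictor])

    @property
    def se(self) -> float:
        return float(self.bse[self.model.spec.predictor])

    @property
    def pvalue(self) -> float:
        return float(self.pvalues[self.model.spec.predictor])

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "site": self._full.sigma2_site,
            "family": self._full.sigma2_family,
            "residual": self._full.sigma2,
        }

    @property
    def marginal_r2_full(self) -> float:
        return marginal_r2(self._full, self.model._X_full)

    @property
    def marginal_r2_delta(self) -> float:
        return marginal_r2_delta(
            self._full, self.model._X_full, self._reduced, self.model._X_reduced
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._full.conf_int(alpha)
        return pd.DataFrame(ci, index=self._full.exog_names, columns=["lower", "upper"])

    def summary(self) -> str:
        spec = self.model.spec
        vc = self.variance_components
        ci = self.conf_int().loc[spec.predictor]
        lines = [
            "Nested linear mixed model (REML): random intercepts site, family-in-site",
            f"Outcome: {spec.outcome}   Predictor: {spec.predictor}   n = {self.nobs}",
            f"standardization: {spec.standardize}   dropped (incomplete): {self.model.n_dropped}",
            "-" * 72,
            f"{'term':<24}{'beta':>10}{'se':>10}{'z':>8}{'p':>12}",
        ]
        for name in self.params.index:
            b, s = self.params[name], self.bse[name]
            lines.append(
                f"{name:<24}{b:>10.4f}{s:>10.4f}{b / s:>8.2f}{self.pvalues[name]:>12.3g}"
            )
        lines += [
            "-" * 72,
            f"PGS 95% CI: [{ci['lower']:.4f}, {ci['upper']:.4f}]",
            f"variance components: site={vc['site']:.4g} family={vc['family']:.4g} "
            f"residual={vc['residual']:.4g}",
            f"marginal R2 (full) = {self.marginal_r2_full:.4f}; "
            f"delta vs covariate-only = {self.marginal_r2_delta:.6f}",
        ]
        return "\n".join(lines)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> PGSAssociationResults:
    """Functional entry point: build and fit one association model."""
    return PGSAssociationModel(data, spec).fit()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class BatteryResults:
    """Association battery output for one or more ancestry groups."""

    table: pd.DataFrame
    alpha: float = 0.05
    group_sizes: dict[str, int] = field(default_factory=dict)

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["p_fdr"] <= self.alpha]

    def summary(self) -> str:
        lines = [
            f"PGS association battery: {len(self.table)} tests, "
            f"BH-FDR within group at q <= {self.alpha}",
        ]
        for grp, g in self.table.groupby("group"):
            n = self.group_sizes.get(grp, g["n_used"].max())
            lines.append(f"\n[{grp}] n = {n}")
            lines.append(
                f"{'predictor':<26}{'outcome':<10}{'beta':>9}{'se':>8}{'p':>11}{'p_fdr':>11}{'dR2m':>10}"
            )
            for _, r in g.iterrows():
                star = " *" if r["p_fdr"] <= self.alpha else ""
                lines.append(
                    f"{r['predictor']:<26}{r['outcome']:<10}{r['beta']:>9.4f}"
                    f"{r['se']:>8.4f}{r['p']:>11.3g}{r['p_fdr']:>11.3g}"
                    f"{r['r2m_delta']:>10.6f}{star}"
                )
        return "\n".join(lines)


def run_association_battery(
    data: pd.DataFrame,
    predictors,
    outcomes=OUTCOMES,
    group_col: str = "ancestry",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    site_col: str = "site_id",
    family_col: str = "family_id",
    standardize: str = "both",
    alpha: float = 0.05,
) -> BatteryResults:
    """Per ancestry group: fit every (predictor, outcome) model and BH-adjust
    the group's p-values.  One reduced (covariate-only) fit is shared per
    outcome within a group.
    """
    predictors = list(predictors)
    outcomes = list(outcomes)
    rows = []
    group_sizes = {}
    for grp, gdata in data.groupby(group_col, sort=True):
        group_sizes[str(grp)] = len(gdata)
        reduced_cache: dict = {}
        for outcome in outcomes:
            for pred in predictors:
                cols = [outcome, pred, *covariates, site_col, family_col]
                sub = gdata[cols].dropna()
                if len(sub) < 50:
                    raise ValueError(
                        f"group {grp!r}, {pred} x {outcome}: only {len(sub)} complete rows"
                    )
                y = sub[outcome].to_numpy(dtype=float)
                x = sub[pred].to_numpy(dtype=float)
                if standardize in ("both", "predictor"):
                    x = _zscore(x)
                if standardize == "both":
                    y = _zscore(y)
                C = sub[list(covariates)].to_numpy(dtype=float)
                site = sub[site_col].to_numpy()
                family = sub[family_col].to_numpy()
                # the covariate-only fit is shared across predictors that use
                # the exact same rows (standardized y is row-set determined)
                key = (
                    outcome,
                    len(sub),
                    int(pd.util.hash_pandas_object(sub.index).sum()),
                )
                if key not in reduced_cache:
                    X_red = np.column_stack([np.ones(len(sub)), C])
                    reduced_cache[key] = (NestedLMM(y, X_red, site, family).fit(), X_red)
                reduced, X_red = reduced_cache[key]
                X_full = np.column_stack([np.ones(len(sub)), x, C])
                full = NestedLMM(
                    y, X_full, site, family, exog_names=["const", pred, *covariates]
                ).fit(start_theta=reduced.theta)
                rows.append(
                    {
                        "group": str(grp),
                        "predictor": pred,
                        "outcome": outcome,
                        "beta": full.params[1],
                        "se": full.bse[1],
                        "p": full.pvalues[1],
                        "r2m_delta": marginal_r2(full, X_full) - marginal_r2(reduced, X_red),
                        "n_used": full.n,
                    }
                )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for grp in table["group"].unique():
        m = table["group"] == grp
        table.loc[m, "p_fdr"] = bh_adjust(table.loc[m, "p"].to_numpy())
    table = table[
        ["group", "predictor", "outcome", "beta", "se", "p", "p_fdr", "r2m_delta", "n_used"]
    ]
    return BatteryResults(table=table, alpha=alpha, group_sizes=group_sizes)
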