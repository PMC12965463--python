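"""Adjacent-grade contrast models: PR, IRR and GMR estimation.

Three model families, each stratified by siting period and fit on an
adjacent-grade two-group subset (D vs C, C vs B, B vs A; the indicator is 1
for the worse grade):

* binary siting outcomes — log-link Poisson with heteroskedasticity-robust
  (HC0 sandwich) variance; the exponentiated indicator coefficient is a
  prevalence ratio (PR);
* plant counts — negative binomial (NB2) with dispersion estimated by
  maximum likelihood; incidence rate ratio (IRR);
* present-day log-transformed emissions burdens — ordinary least squares;
  geometric mean ratio (GMR), restricted to neighbourhoods with at least
  one operable-2019 plant upwind.

Model 1 adjusts for the pre-1940 baseline plant flag and census region;
Model 2 additionally adjusts for log 1940 city population and the seven
1940 HOLC-appraisal covariates, complete-case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CONTRASTS",
    "SES_COVARIATES",
    "ModelResult",
    "contrast_subset",
    "fit_prevalence_ratio",
    "fit_incidence_rate_ratio",
    "fit_gmr",
    "run_model_suite",
]

#: (worse grade, better grade) per adjacent contrast.
CONTRASTS = {"D_vs_C": ("D", "C"), "C_vs_B": ("C", "B"), "B_vs_A": ("B", "A")}

REGIONS = ("Northeast", "Midwest", "South", "West")

#: The seven 1940 neighbourhood covariates from HOLC area description sheets.
SES_COVARIATES = (
    "pct_foreign_born",
    "pct_black",
    "median_household_income",
    "median_building_age",
    "occupation",
    "repair_status",
    "mortgage_availability",
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ModelResult:
    outcome: str
    contrast: str
    period: str
    radius_km: float
    covariate_set: str
    family: str
    estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    log_se: float = np.nan
    n_used: int = 0
    n_dropped_missing: int = 0
    n_dropped_zero: int = 0
    converged: bool = False
    dispersion: float = np.nan
    message: str = ""

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def contrast_subset(data: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Restrict to the two grades of an adjacent contrast and add the
    worse-grade indicator column ``worse_grade``."""
    worse, better = CONTRASTS[contrast]
    present = set(data["grade"].unique())
    for g in (worse, better):
        if g not in present:
            raise ValueError(f"grade {g!r} absent from data for contrast {contrast}")
    sub = data.loc[data["grade"].isin([worse, better])].copy()
    sub["worse_grade"] = (sub["grade"] == worse).astype(int)
    return sub


def _design(data: pd.DataFrame, covariate_set: str, extra_covariates: bool = True):
    """Build (X, n_dropped_missing, kept_index).

    model1: intercept + indicator + baseline flag + region dummies;
    model2 adds log city population and the seven 1940 covariates,
    complete-case.  ``extra_covariates=False`` fits indicator-only (used by
    closed-form toy checks).
    """
    cols = {"const": 1.0, "worse_grade": data["worse_grade"].astype(float)}
    if extra_covariates:
        if "baseline_any_pre1940" in data:
            cols["baseline_any_pre1940"] = data["baseline_any_pre1940"].astype(float)
        if "region" in data:
            # first region in fixed order is the reference level
            present = [r for r in REGIONS if r in set(data["region"])]
            for r in present[1:]:
                cols[f"region_{r}"] = (data["region"] == r).astype(float)
        if covariate_set == "model2":
            if "city_population_1940" in data:
                with np.errstate(divide="ignore"):
                    cols["log_city_population"] = np.log(
                        data["city_population_1940"].astype(float)
                    )
            for c in SES_COVARIATES:
                if c in data:
                    cols[c] = data[c].astype(float)
    X = pd.DataFrame(cols, index=data.index)
    keep = X.notna().all(axis=1) & np.isfinite(X).all(axis=1)
    return X.loc[keep], int((~keep).sum()), keep


def _wald_from_fit(res, result: ModelResult, param: str = "worse_grade") -> ModelResult:
    coef = res.params[param]
    se = res.bse[param]
    result.estimate = float(np.exp(coef))
    result.ci_low = float(np.exp(coef - Z95 * se))
    result.ci_high = float(np.exp(coef + Z95 * se))
    result.log_se = float(se)
    return result


def fit_prevalence_ratio(
    data: pd.DataFrame, outcome: str, *, covariate_set: str = "model1",
    use_covariates: bool = True, **meta,
) -> ModelResult:
    """Log-link Poisson on a binary outcome with HC0 sandwich variance.

    PR = exp(worse-grade coefficient); Wald 95% CI on the log scale.  An
    outcome that is all-zero (or all-one) in either grade group is flagged
    as non-converged (separation) rather than silently reported.
    """
    result = ModelResult(
        outcome=outcome, family="poisson_robust", covariate_set=covariate_set,
        **{k: meta.get(k, v) for k, v in
           dict(contrast="", period="", radius_km=np.nan).items()},
    )
    y = data[outcome].astype(float)
    X, result.n_dropped_missing, keep = _design(data, covariate_set, use_covariates)
    y = y.loc[keep]
    result.n_used = len(y)
    for grp in (0, 1):
        ymask = y[X["worse_grade"] == grp]
        if len(ymask) == 0 or ymask.sum() == 0:
            result.message = f"outcome all-zero or empty in group {grp} (separation)"
            return result
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                cov_type="HC0", tol=1e-12, maxiter=200
            )
        result.converged = bool(fit.converged)
    except Exception as exc:  # pragma: no cover - defensive
        result.message = f"fit failed: {exc}"
        return result
    return _wald_from_fit(fit, result)


def fit_incidence_rate_ratio(
    data: pd.DataFrame, outcome: str, *, covariate_set: str = "model1",
    use_covariates: bool = True, **meta,
) -> ModelResult:
    """NB2 negative binomial on a count outcome, dispersion by full ML.

    IRR = exp(worse-grade coefficient) with a Wald 95% CI.  A dispersion
    estimate at the zero boundary (Poisson limit) is flagged, not an error.
    """
    result = ModelResult(
        outcome=outcome, family="negative_binomial", covariate_set=covariate_set,
        **{k: meta.get(k, v) for k, v in
           dict(contrast="", period="", radius_km=np.nan).items()},
    )
    y = data[outcome]
    arr = y.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("count outcome must be non-negative integers")
    X, result.n_dropped_missing, keep = _design(data, covariate_set, use_covariates)
    y = y.loc[keep].astype(float)
    result.n_used = len(y)
    if y.sum() == 0:
        result.message = "outcome all-zero (no events)"
        return result
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, loglike_method="nb2")
            fit = model.fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False):
                fit = model.fit(disp=0, maxiter=500, method="nm", start_params=fit.params)
        result.converged = bool(fit.mle_retvals.get("converged", False))
        alpha = float(fit.params.iloc[-1])
        result.dispersion = alpha
        if alpha < 1e-6:
            result.message = "dispersion at zero boundary (Poisson limit)"
    except Exception as exc:
        result.message = f"fit failed: {exc}"
        return result
    return _wald_from_fit(fit, result)


def fit_gmr(
    data: pd.DataFrame, outcome: str, *, covariate_set: str = "model1",
    use_covariates: bool = True, min_rows: int = 10, **meta,
) -> ModelResult:
    """OLS of log(outcome) on the worse-grade indicator (+ covariates).

    GMR = exp(worse-grade coefficient); classical 95% CI.  Rows are expected
    to be pre-restricted to neighbourhoods with an operable-2019 plant
    upwind; residual zero burdens (possible only through zero-imputed
    missing emissions) are dropped with a logged count since log(0) is
    undefined.
    """
    result = ModelResult(
        outcome=outcome, family="log_linear", covariate_set=covariate_set,
        **{k: meta.get(k, v) for k, v in
           dict(contrast="", period="present_day", radius_km=np.nan).items()},
    )
    positive = data[outcome] > 0
    result.n_dropped_zero = int((~positive).sum())
    data = data.loc[positive]
    y = np.log(data[outcome].astype(float))
    X, result.n_dropped_missing, keep = _design(data, covariate_set, use_covariates)
    y = y.loc[keep]
    result.n_used = len(y)
    if result.n_used < min_rows:
        result.message = f"only {result.n_used} usable rows (< {min_rows}); refusing to fit"
        return result
    if X["worse_grade"].nunique() < 2:
        result.message = "indicator constant after restriction"
        return result
    fit = sm.OLS(y, X).fit()
    result.converged = True
    return _wald_from_fit(fit, result)


BINARY_OUTCOMES = ("any_fossil", "any_coal_oil", "any_peaker")
SITING_PERIODS = ("1940_1969", "1970_1999", "2000_2019")
BURDEN_OUTCOMES = ("nox_burden", "so2_burden", "pm25_burden")


def run_model_suite(
    exposure: pd.DataFrame,
    areas: pd.DataFrame,
    radii_km=(5.0,),
    covariate_sets=("model1",),
) -> pd.DataFrame:
    """Fit the full contrast grid and return a tidy results table.

    Per radius and covariate set: 3 contrasts x (3 binary outcomes x 3
    periods PR + 3 periods IRR + 3 burden GMRs) = 45 rows.  Per-fit failures
    are captured in rows (converged=False with a message), never fatal.
    """
    area_cols = ["area_id", "grade", "region", "city_population_1940", *SES_COVARIATES]
    area_cols = [c for c in area_cols if c in areas.columns]
    merged = exposure.merge(areas[area_cols], on="area_id", validate="m:1")

    rows = []
    for radius in radii_km:
        at_r = merged.loc[merged["radius_km"] == radius]
        if at_r.empty:
            raise ValueError(f"exposure table has no rows at radius {radius} km")
        for covset in covariate_sets:
            for contrast in CONTRASTS:
                sub = contrast_subset(at_r, contrast)
                meta = dict(contrast=contrast, radius_km=radius)
                for period in SITING_PERIODS:
                    for out in BINARY_OUTCOMES:
                        res = fit_prevalence_ratio(
                            sub, f"{out}_{period}", covariate_set=covset,
                            period=period, **meta,
                        )
                        res.outcome = out
                        rows.append(res.to_row())
                    res = fit_incidence_rate_ratio(
                        sub, f"n_fossil_{period}", covariate_set=covset,
                        period=period, **meta,
                    )
                    res.outcome = "n_fossil"
                    rows.append(res.to_row())
                restricted = sub.loc[sub["has_operable_upwind_2019"]]
                for out in BURDEN_OUTCOMES:
                    res = fit_gmr(restricted, out, covariate_set=covset, **meta)
                    rows.append(res.to_row())
    return pd.DataFrame(rows)
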