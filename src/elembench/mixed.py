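"""Variance partitioning for element concentrations with nested random effects.

For each element a Gaussian linear mixed model is fitted by REML with random
intercepts for population and for growth year nested within population, and
fixed effects for sampling covariates (collection method, age class, sex).
Explained variance is summarised with the Nakagawa-Schielzeth R² pair:

    R²m = var_fixed / (var_fixed + var_pop + var_year + var_resid)
    R²c = (var_fixed + var_pop + var_year) / (same denominator)

Concentrations are right-skewed, so the response is log-transformed either
always, never, or by an automatic rule (|skewness of the fixed-effects OLS
residuals| > 1) — the workflow's reproducible stand-in for visual Q-Q
inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


class DegenerateDesignError(ValueError):
    """A fixed-effect covariate is constant (or otherwise rank-deficient)."""


@dataclass
class MixedModelFit:
    element: str
    response_transform: str  # "identity" | "log"
    fixed_effects: dict[str, tuple[float, float]]  # term -> (estimate, SE)
    var_population: float
    var_year_within_population: float
    var_residual: float
    var_fixed: float
    loglik_reml: float
    n: int


def _choose_transform(values: np.ndarray, design: pd.DataFrame, fixed_terms) -> str:
    if not (values > 0).all():
        return "identity"
    if fixed_terms:
        X = pd.get_dummies(design[list(fixed_terms)], drop_first=True, dtype=float)
        X = sm.add_constant(X, has_constant="add")
        resid = sm.OLS(values, X).fit().resid
    else:
        resid = values - values.mean()
    return "log" if abs(float(stats.skew(resid))) > 1.0 else "identity"


def fit_lmm(table: pd.DataFrame, element: str, fixed_terms=(),
            transform: str = "auto") -> MixedModelFit:
    """REML fit of the nested random-intercept model for one element.

    Records with a missing response or missing value of any fixed term are
    excluded. ``transform`` is "auto", "log" or "identity".
    """
    cols = ["population", "growth_year", element, *fixed_terms]
    data = table[cols].dropna().copy()
    if data["population"].nunique() < 2:
        raise ValueError("need at least two populations")
    for term in fixed_terms:
        if data[term].nunique() < 2:
            raise DegenerateDesignError(f"fixed term {term!r} is constant in the data")
    if transform == "auto":
        transform = _choose_transform(data[element].to_numpy(float), data, fixed_terms)
    if transform == "log":
        if not (data[element] > 0).all():
            raise ValueError("log transform requires strictly positive concentrations")
        data["_y"] = np.log(data[element].astype(float))
    elif transform == "identity":
        data["_y"] = data[element].astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    data["growth_year"] = data["growth_year"].astype(int).astype(str)

    rhs = " + ".join(f"C({t})" for t in fixed_terms) if fixed_terms else "1"
    # a single year per population leaves the nested component unidentifiable
    has_year_level = data.groupby("population")["growth_year"].nunique().max() > 1
    vc = {"year": "0 + C(growth_year)"} if has_year_level else None
    model = smf.mixedlm(
        f"_y ~ {rhs}", data,
        groups="population", re_formula="1",
        vc_formula=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not np.all(np.isfinite(result.fe_params)):
        raise DegenerateDesignError("non-finite fixed-effect estimates")

    fe = {name: (float(est), float(se))
          for name, est, se in zip(result.fe_params.index, result.fe_params,
                                   result.bse_fe)}
    # variance of the fixed-effect linear predictor over the estimation sample
    fitted_fixed = np.asarray(model.exog) @ np.asarray(result.fe_params)
    var_fixed = float(np.var(fitted_fixed, ddof=1)) if len(fitted_fixed) > 1 else 0.0

    return MixedModelFit(
        element=element,
        response_transform=transform,
        fixed_effects=fe,
        var_population=float(np.asarray(result.cov_re)[0, 0]),
        var_year_within_population=float(result.vcomp[0]) if len(result.vcomp) else 0.0,
        var_residual=float(result.scale),
        var_fixed=var_fixed,
        loglik_reml=float(result.llf),
        n=int(len(data)),
    )


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """(marginal, conditional) R² of a fitted mixed model."""
    denom = (fit.var_fixed + fit.var_population
             + fit.var_year_within_population + fit.var_residual)
    if denom <= 0:
        raise ValueError("all variance components are zero; R² undefined")
    r2m = fit.var_fixed / denom
    r2c = (fit.var_fixed + fit.var_population + fit.var_year_within_population) / denom
    return float(r2m), float(r2c)


def partition_variance(table: pd.DataFrame, elements, fixed_terms=("collection", "age_class", "sex"),
                       transform: str = "auto") -> pd.DataFrame:
    """R²m / R²c table across elements (one row per element)."""
    rows = []
    for el in elements:
        fit = fit_lmm(table, el, fixed_terms=fixed_terms, transform=transform)
        r2m, r2c = r2_nakagawa(fit)
        rows.append({
            "element": el,
            "transform": fit.response_transform,
            "n": fit.n,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "var_population": fit.var_population,
            "var_year_within_population": fit.var_year_within_population,
            "var_residual": fit.var_residual,
            "var_fixed": fit.var_fixed,
        })
    return pd.DataFrame(rows)
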