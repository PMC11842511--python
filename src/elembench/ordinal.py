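"""Proportional-odds regression of population trend on scaled element
concentrations, and extraction of concentration benchmarks from predicted
probability curves.

The model is the cumulative-logit proportional-odds model on the ordered
trend (declining < stable < increasing):

    P(trend <= k | x) = logistic(zeta_k - x' beta),   zeta_1 < zeta_2

so beta > 0 means higher concentration shifts probability mass toward
increasing, and exp(beta) is the odds ratio per 1 SD of concentration
(predictors are z-scaled). From a fitted model, each element's probability
curve is traced on the µg/g scale with all other predictors held at their
means, and two decision thresholds are read off:

* the 'limit' benchmark — the concentration at which the probability of a
  declining trend crosses a stated level (default 0.45); populations below
  it (above it, for negatively associated elements) are more likely
  declining;
* the 'target' benchmark — the concentration at which the probability of an
  increasing trend crosses the level; populations above it are more likely
  increasing. Only defined for positively associated elements.

A benchmark is reported as absent when the curve never reaches the level
inside the observed concentration range: thresholds extrapolated beyond the
data are not defensible for management use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .qc import TREND_LEVELS


class ConvergenceError(RuntimeError):
    """The likelihood maximisation did not converge (e.g. separation)."""


class ConcentrationScaler(TransformerMixin, BaseEstimator):
    """Column-wise z-scaling with the sample SD (ddof=1).

    Stores per-column (mean, SD) so the transform inverts exactly; raises on
    constant columns.
    """

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0) or np.any(~np.isfinite(self.scale_)):
            names = getattr(self, "feature_names_in_", np.arange(X.shape[1]))
            bad = list(np.asarray(names)[(self.scale_ == 0) | ~np.isfinite(self.scale_)])
            raise ValueError(f"constant or degenerate column(s): {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        cols = isinstance(X, pd.DataFrame)
        idx = X.index if cols else None
        arr = (np.asarray(X, float) - self.mean_) / self.scale_
        if cols:
            return pd.DataFrame(arr, index=idx, columns=self.feature_names_in_)
        return arr

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, float) * self.scale_ + self.mean_

    def params_for(self, element) -> tuple[float, float]:
        check_is_fitted(self, "mean_")
        names = list(getattr(self, "feature_names_in_", []))
        if element not in names:
            raise ValueError(f"{element!r} was not scaled by this scaler")
        j = names.index(element)
        return float(self.mean_[j]), float(self.scale_[j])


def scale_columns(table: pd.DataFrame, elements) -> tuple[pd.DataFrame, ConcentrationScaler]:
    """Z-scale the element columns of a sample table (rows with NaN dropped)."""
    data = table[list(elements)].dropna()
    scaler = ConcentrationScaler().fit(data)
    return scaler.transform(data), scaler


class ProportionalOddsClassifier(ClassifierMixin, BaseEstimator):
    """Cumulative-logit proportional-odds model, fitted by maximum likelihood.

    Parameters
    ----------
    class_order:
        Ordered category labels (lowest first); default the trend levels.
    maxiter, gtol:
        Optimizer budget and gradient-norm tolerance (BFGS).

    Attributes
    ----------
    coef_ : (p,) slope per predictor (per 1 unit; per 1 SD on scaled input)
    cutpoints_ : (k-1,) strictly increasing intercepts of the cumulative logits
    bse_ : (p,) Wald standard errors of coef_
    wald_z_, wald_p_ : (p,) Wald z statistics and two-sided p-values
    loglik_ : maximised log-likelihood
    n_ : number of observations
    """

    def __init__(self, class_order=TREND_LEVELS, maxiter=500, gtol=1e-6):
        self.class_order = class_order
        self.maxiter = maxiter
        self.gtol = gtol

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xarr = X.to_numpy(float)
        else:
            Xarr = np.asarray(X, float)
            if Xarr.ndim == 1:
                Xarr = Xarr[:, None]
        order = [c for c in self.class_order if c in set(np.asarray(y, dtype=object))]
        if len(order) < 2:
            raise ValueError("y must contain at least two ordered categories")
        if np.linalg.matrix_rank(Xarr - Xarr.mean(0)) < Xarr.shape[1]:
            raise ValueError("design matrix is rank deficient")
        endog = pd.Series(pd.Categorical(np.asarray(y, dtype=object),
                                         categories=order, ordered=True))
        model = OrderedModel(endog, Xarr, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=self.maxiter,
                            gtol=self.gtol, disp=False)
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                "proportional-odds fit did not converge (possible complete "
                f"separation); |params| max = {np.max(np.abs(res.params)):.3g}")
        p = Xarr.shape[1]
        params = np.asarray(res.params, float)
        self.classes_ = np.asarray(order, dtype=object)
        self.coef_ = params[:p]
        self.cutpoints_ = np.asarray(
            model.transform_threshold_params(params)[1:-1], float)
        self.bse_ = np.asarray(res.bse, float)[:p]
        self.wald_z_ = self.coef_ / self.bse_
        self.wald_p_ = 2 * stats.norm.sf(np.abs(self.wald_z_))
        self.loglik_ = float(res.llf)
        self.n_ = int(len(endog))
        self.n_features_in_ = p
        self._result = res
        return self

    @property
    def elements_(self):
        return list(getattr(self, "feature_names_in_",
                            [f"x{i}" for i in range(self.n_features_in_)]))

    def _linpred(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[list(self.feature_names_in_)]
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def predict_proba(self, X):
        eta = self._linpred(X)
        cum = expit(self.cutpoints_[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score_samples_loglik(self, X, y):
        """Log-likelihood of (X, y) under the fitted parameters."""
        P = self.predict_proba(X)
        idx = {c: i for i, c in enumerate(self.classes_)}
        cols = np.array([idx[v] for v in np.asarray(y, dtype=object)])
        return float(np.log(P[np.arange(len(cols)), cols]).sum())


def fit_proportional_odds(X, y, **kwargs) -> ProportionalOddsClassifier:
    """Thin functional wrapper over :class:`ProportionalOddsClassifier`."""
    return ProportionalOddsClassifier(**kwargs).fit(X, y)


def lr_test(full: ProportionalOddsClassifier, reduced: ProportionalOddsClassifier
            ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested proportional-odds fits."""
    full_set, red_set = set(full.elements_), set(reduced.elements_)
    if not red_set < full_set:
        raise ValueError("models are not nested (reduced predictors must be a "
                         "strict subset of the full model's)")
    if full.n_ != reduced.n_:
        raise ValueError("models were fitted on different numbers of observations")
    df = len(full_set) - len(red_set)
    chi2 = 2.0 * (full.loglik_ - reduced.loglik_)
    chi2 = max(chi2, 0.0)
    return float(chi2), df, float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0


def odds_ratio_table(fit: ProportionalOddsClassifier, confidence: float = 0.95
                     ) -> pd.DataFrame:
    """Per-predictor odds ratio with a Wald confidence interval."""
    z = stats.norm.ppf(0.5 + confidence / 2)
    rows = []
    for name, b, se, wz, wp in zip(fit.elements_, fit.coef_, fit.bse_,
                                   fit.wald_z_, fit.wald_p_):
        rows.append({
            "element": name, "beta": float(b), "se": float(se),
            "z": float(wz), "p": float(wp),
            "odds_ratio": float(np.exp(b)),
            "ci_lower": float(np.exp(b - z * se)),
            "ci_upper": float(np.exp(b + z * se)),
        })
    return pd.DataFrame(rows)


@dataclass
class ProbabilityCurve:
    element: str
    grid: np.ndarray                  # concentrations, µg/g
    p_declining: np.ndarray
    p_stable: np.ndarray
    p_increasing: np.ndarray
    covariate_context: str
    beta: float                       # slope for this element (per SD)
    cutpoints: np.ndarray
    scale_mean: float
    scale_sd: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration": self.grid,
            "p_declining": self.p_declining,
            "p_stable": self.p_stable,
            "p_increasing": self.p_increasing,
        })


def probability_curve(fit: ProportionalOddsClassifier, element: str,
                      scaler: ConcentrationScaler,
                      grid_range: tuple[float, float], n_grid: int = 201
                      ) -> ProbabilityCurve:
    """Category probabilities along one element's concentration axis.

    All other predictors are held at 0 on the scaled scale, i.e. at their
    estimation-sample means.
    """
    names = fit.elements_
    if element not in names:
        raise ValueError(f"{element!r} is not a predictor of this fit")
    j = names.index(element)
    mean, sd = scaler.params_for(element)
    grid = np.linspace(grid_range[0], grid_range[1], n_grid)
    z = (grid - mean) / sd
    eta = z * fit.coef_[j]
    cum1 = expit(fit.cutpoints_[0] - eta)
    cum2 = expit(fit.cutpoints_[1] - eta) if len(fit.cutpoints_) > 1 else np.ones_like(cum1)
    return ProbabilityCurve(
        element=element, grid=grid,
        p_declining=cum1, p_stable=cum2 - cum1, p_increasing=1.0 - cum2,
        covariate_context="other predictors at estimation-sample means",
        beta=float(fit.coef_[j]), cutpoints=np.asarray(fit.cutpoints_, float),
        scale_mean=mean, scale_sd=sd,
    )


@dataclass
class ElementBenchmarks:
    element: str
    limit: Optional[float]
    target: Optional[float]
    p_level: float
    direction: str  # "positive" | "negative"


def _within(x: float, lo: float, hi: float) -> Optional[float]:
    return float(x) if lo <= x <= hi else None


def extract_benchmarks(curve: ProbabilityCurve, p_level: float = 0.45,
                       rule: str = "fixed-level") -> ElementBenchmarks:
    """Read 'limit' and 'target' thresholds off a probability curve.

    rule="fixed-level": the concentration where p(declining) (limit) or
    p(increasing) (target) equals ``p_level``; the cumulative-logit form is
    inverted in closed form, then clipped to the curve's grid range (absent
    if outside). rule="category-crossing": the concentration where the
    declining (resp. increasing) probability overtakes the stable one.
    """
    if not 1.0 / 3.0 < p_level < 1.0:
        raise ValueError("p_level must be in (1/3, 1)")
    for vec in (curve.p_declining, curve.p_increasing):
        d = np.diff(vec)
        if not ((d >= -1e-12).all() or (d <= 1e-12).all()):
            raise ValueError("probability vector is not monotone; inconsistent curve")
    beta, (z1, z2) = curve.beta, curve.cutpoints
    mean, sd = curve.scale_mean, curve.scale_sd
    lo, hi = float(curve.grid.min()), float(curve.grid.max())
    direction = "positive" if beta > 0 else "negative"
    if beta == 0:
        return ElementBenchmarks(curve.element, None, None, p_level, "positive")

    def conc(zscaled: float) -> float:
        return mean + sd * zscaled

    if rule == "fixed-level":
        # p_declining(x) = expit(z1 - beta z) = p  =>  z = (z1 - logit(p)) / beta
        limit = _within(conc((z1 - logit(p_level)) / beta), lo, hi)
        if direction == "positive":
            # p_increasing(x) = 1 - expit(z2 - beta z) = p
            target = _within(conc((z2 - logit(1.0 - p_level)) / beta), lo, hi)
        else:
            target = None
    elif rule == "category-crossing":
        def f_limit(z):  # p_declining - p_stable
            e = beta * z
            return 2 * expit(z1 - e) - expit(z2 - e)

        def f_target(z):  # p_increasing - p_stable
            e = beta * z
            return 1 - 2 * expit(z2 - e) + expit(z1 - e)

        zlo, zhi = (lo - mean) / sd, (hi - mean) / sd
        limit = target = None
        if f_limit(zlo) * f_limit(zhi) < 0:
            limit = conc(optimize.brentq(f_limit, zlo, zhi))
        if direction == "positive" and f_target(zlo) * f_target(zhi) < 0:
            target = conc(optimize.brentq(f_target, zlo, zhi))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ElementBenchmarks(curve.element, limit, target, p_level, direction)


def benchmarks_for_elements(fit: ProportionalOddsClassifier,
                            scaler: ConcentrationScaler,
                            table: pd.DataFrame,
                            p_level: float = 0.45, rule: str = "fixed-level",
                            n_grid: int = 201
                            ) -> tuple[list[ElementBenchmarks], dict[str, ProbabilityCurve]]:
    """Per-element curves and benchmarks, searched within the observed range."""
    curves: dict[str, ProbabilityCurve] = {}
    out: list[ElementBenchmarks] = []
    for el in fit.elements_:
        vals = table[el].dropna()
        rng = (float(vals.min()), float(vals.max()))
        curve = probability_curve(fit, el, scaler, rng, n_grid=n_grid)
        curves[el] = curve
        out.append(extract_benchmarks(curve, p_level=p_level, rule=rule))
    return out, curves
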