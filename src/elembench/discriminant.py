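"""Trend discrimination from element profiles: MANOVA screen, LDA, LOOCV,
and linear-discriminant-scale benchmarks.

The discriminant follows the classical multi-group construction: with pooled
within-group covariance ``Sw`` (divisor n - g) and between-group scatter
``B = sum_k n_k (mu_k - mu)(mu_k - mu)'``, the discriminant directions are
the leading eigenvectors of the generalized problem ``B v = theta W v``
(``W`` the raw within scatter), rescaled so that the within-group covariance
of the discriminant scores is the identity. That is the scaling under which
the familiar printed coefficient vectors of discriminant analyses arise, and
it makes classification by nearest centroid (plus log-priors) in score space
exactly the Gaussian equal-covariance rule.

Wilks' lambda = det(W)/det(W + B) = prod 1/(1 + theta_i) links the MANOVA
and the LDA: both code paths must agree on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class CollinearityError(ValueError):
    """Within-group covariance is singular; names the implicated columns."""


# ---------------------------------------------------------------------------
# group summaries and MANOVA


def group_summary(table: pd.DataFrame, elements, group_col: str = "trend",
                  confidence: float = 0.95) -> pd.DataFrame:
    """Per-group mean with a t confidence interval, one row per (element, group)."""
    rows = []
    for el in elements:
        for grp, vals in table.groupby(group_col, observed=True)[el]:
            vals = vals.dropna().to_numpy(float)
            n = len(vals)
            if n < 2:
                raise ValueError(f"group {grp!r} has {n} observation(s) for {el}; CI undefined")
            mean = float(vals.mean())
            se = float(vals.std(ddof=1)) / np.sqrt(n)
            tq = stats.t.ppf(0.5 + confidence / 2, n - 1)
            rows.append({"element": el, "group": grp, "n": n, "mean": mean,
                         "ci_lower": mean - tq * se, "ci_upper": mean + tq * se})
    return pd.DataFrame(rows)


@dataclass
class ManovaResult:
    statistic_name: str
    wilks_lambda: float
    f_approx: float
    df_num: float
    df_den: float
    p: float
    univariate: pd.DataFrame  # element, F, df_num, df_den, p


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    mu = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    means = {}
    for c, n_k in zip(classes, counts):
        Xk = X[y == c]
        mk = Xk.mean(axis=0)
        means[c] = mk
        D = Xk - mk
        W += D.T @ D
        d = (mk - mu)[:, None]
        B += n_k * (d @ d.T)
    return W, B, means, classes, counts, mu


def _check_within(W: np.ndarray, names) -> None:
    if np.linalg.cond(W) > 1e10:
        evals, evecs = np.linalg.eigh(W)
        bad = evecs[:, 0]
        worst = [names[i] for i in np.argsort(-np.abs(bad))[:3]]
        raise CollinearityError(
            f"within-group matrix is (near-)singular; implicated columns: {worst}")


def manova_wilks(table: pd.DataFrame, elements, group_col: str = "trend") -> ManovaResult:
    """One-way MANOVA with Wilks' lambda and Rao's F approximation.

    Also returns the per-element univariate one-way ANOVA F tests.
    """
    elements = list(elements)
    data = table[[group_col, *elements]].dropna()
    X = data[elements].to_numpy(float)
    y = np.asarray(data[group_col])
    groups = pd.unique(y)
    g = len(groups)
    n, p = X.shape
    if g < 2:
        raise ValueError("need at least two groups")
    if n <= p + g:
        raise ValueError("too few observations for a MANOVA of this dimension")

    W, B, *_ = _scatter_matrices(X, y)
    _check_within(W, elements)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))

    nu_h, nu_e = g - 1, n - g
    denom = p ** 2 + nu_h ** 2 - 5
    t = np.sqrt((p ** 2 * nu_h ** 2 - 4) / denom) if denom > 0 else 1.0
    w = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df1 = p * nu_h
    df2 = w * t - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))

    uni_rows = []
    for j, el in enumerate(elements):
        samples = [X[y == c, j] for c in groups]
        F_el, p_el = stats.f_oneway(*samples)
        uni_rows.append({"element": el, "F": float(F_el),
                         "df_num": g - 1, "df_den": n - g, "p": float(p_el)})
    return ManovaResult("Wilks", lam, float(F), float(df1), float(df2), pval,
                        pd.DataFrame(uni_rows))


def screen_elements(table: pd.DataFrame, elements, group_col: str = "trend",
                    alpha: float = 0.05) -> list[str]:
    """Elements whose univariate one-way F test has p < alpha."""
    res = manova_wilks(table, elements, group_col=group_col)
    keep = res.univariate.loc[res.univariate["p"] < alpha, "element"]
    return [el for el in elements if el in set(keep)]


# ---------------------------------------------------------------------------
# the discriminant estimator


class TrendDiscriminant(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Multi-group linear discriminant analysis with ordered classes.

    Parameters
    ----------
    class_order:
        Explicit class ordering (lowest first), e.g.
        ``("declining", "stable", "increasing")``. Defaults to the ordered
        categories of a categorical ``y``, else sorted unique labels. The
        ordering fixes discriminant signs (highest-class centroid on the
        positive side) and breaks posterior ties toward the lowest class.
    priors:
        Class prior weights (mapping class -> weight, normalised internally);
        defaults to observed frequencies.
    standardize:
        If True, z-scale predictors (sample SD) before fitting; coefficients
        are then per-SD. Default False: predictors enter on their measured
        µg/g scale, the convention under which hair-element discriminant
        coefficients are usually printed.

    Attributes
    ----------
    classes_ : ndarray of class labels in order
    scalings_ : (p, m) discriminant coefficient matrix (within-class
        covariance of scores = identity)
    xbar_ : (p,) prior-weighted mean of class centroids (score origin)
    means_ : (g, p) class means on the predictor scale
    centroids_ : (g, m) class means in discriminant space
    eigenvalues_ : (m,) eigenvalues of W^-1 B (raw scatters)
    trace_proportion_ : (m,) eigenvalue shares, sums to 1
    wilks_lambda_ : float
    """

    def __init__(self, class_order=None, priors=None, standardize=False):
        self.class_order = class_order
        self.priors = priors
        self.standardize = standardize

    def _resolve_classes(self, y):
        if self.class_order is not None:
            order = list(self.class_order)
        elif isinstance(y, pd.Series) and isinstance(y.dtype, pd.CategoricalDtype):
            order = [c for c in y.cat.categories if c in set(y.dropna())]
        elif isinstance(y, pd.Categorical):
            order = [c for c in y.categories if c in set(y.dropna())]
        else:
            order = sorted(pd.unique(np.asarray(y)))
        return np.asarray(order, dtype=object)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
        classes = self._resolve_classes(y)
        y = np.asarray(y, dtype=object)
        present = set(pd.unique(y))
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValueError(f"class_order classes absent from y: {missing}")
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")

        n, p = X.shape
        g = len(classes)
        m = min(p, g - 1)
        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            self.scale_sd_ = X.std(axis=0, ddof=1)
            if np.any(self.scale_sd_ == 0):
                raise ValueError("constant predictor column under standardize=True")
            X = (X - self.scale_mean_) / self.scale_sd_

        W, B, means, _, counts_all, _ = _scatter_matrices(X, y)
        names = list(getattr(self, "feature_names_in_", range(p)))
        _check_within(W, names)

        counts = np.array([np.sum(y == c) for c in classes], float)
        if self.priors is None:
            priors = counts / counts.sum()
        else:
            pr = np.array([self.priors[c] for c in classes], float)
            priors = pr / pr.sum()

        evals, evecs = linalg.eigh(B, W)  # v' W v = I for the returned vectors
        order = np.argsort(evals)[::-1][:m]
        theta = np.clip(evals[order], 0.0, None)
        V = evecs[:, order] * np.sqrt(n - g)  # now v' Sw v = 1, Sw = W/(n-g)

        M = np.stack([means[c] for c in classes])  # class means, predictor scale
        xbar = priors @ M
        cent = (M - xbar) @ V
        # orient: highest class minus lowest class nonnegative on each axis
        for j in range(m):
            s = cent[-1, j] - cent[0, j]
            if s == 0:
                s = V[np.argmax(np.abs(V[:, j])), j]
            if s < 0:
                V[:, j] *= -1
                cent[:, j] *= -1

        self.classes_ = classes
        self.priors_ = priors
        self.means_ = M
        self.xbar_ = xbar
        self.scalings_ = V
        self.centroids_ = cent
        self.eigenvalues_ = theta
        tot = theta.sum()
        self.trace_proportion_ = theta / tot if tot > 0 else np.full(m, np.nan)
        self.wilks_lambda_ = float(np.prod(1.0 / (1.0 + theta)))
        self.n_features_in_ = p
        return self

    def _prepare(self, X):
        check_is_fitted(self, "scalings_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing element column(s): {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if self.standardize:
            X = (X - self.scale_mean_) / self.scale_sd_
        return X

    def transform(self, X):
        """Discriminant scores: (x - xbar) @ scalings."""
        X = self._prepare(X)
        return (X - self.xbar_) @ self.scalings_

    def decision_scores(self, X):
        """Log-posterior (up to a constant) per class in score space."""
        T = self.transform(X)
        d2 = ((T[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return -0.5 * d2 + np.log(self.priors_)

    def predict_proba(self, X):
        S = self.decision_scores(X)
        S = S - S.max(axis=1, keepdims=True)
        P = np.exp(S)
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X):
        # argmax takes the first maximum -> ties resolve to the lowest class
        idx = np.argmax(self.decision_scores(X), axis=1)
        return self.classes_[idx]


def fit_lda(table: pd.DataFrame, elements, group_col: str = "trend",
            **kwargs) -> TrendDiscriminant:
    """Fit :class:`TrendDiscriminant` on the non-missing rows of a sample table."""
    data = table[[group_col, *elements]].dropna()
    order = kwargs.pop("class_order", None)
    if order is None and isinstance(data[group_col].dtype, pd.CategoricalDtype):
        order = [c for c in data[group_col].cat.categories
                 if c in set(data[group_col].unique())]
    est = TrendDiscriminant(class_order=order, **kwargs)
    return est.fit(data[list(elements)], data[group_col].astype(object))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValReport:
    classes: list
    confusion: np.ndarray            # true x predicted counts
    accuracy: float
    adjusted_error_rate: float       # balanced (macro-averaged per-class) error
    raw_error_rate: float
    sensitivity: float               # macro one-vs-rest recall
    specificity: float               # macro one-vs-rest true-negative rate
    per_class: pd.DataFrame          # class, n, sensitivity, specificity

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion,
                            index=pd.Index(self.classes, name="true"),
                            columns=pd.Index(self.classes, name="predicted"))


def confusion_report(y_true, y_pred, classes) -> CrossValReport:
    classes = list(classes)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    C = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    n = C.sum()
    acc = np.trace(C) / n
    per_rows = []
    sens, spec = [], []
    for i, c in enumerate(classes):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        se = tp / (tp + fn) if tp + fn else np.nan
        sp = tn / (tn + fp) if tn + fp else np.nan
        sens.append(se)
        spec.append(sp)
        per_rows.append({"class": c, "n": int(tp + fn),
                         "sensitivity": se, "specificity": sp})
    balanced_err = float(np.nanmean([1 - s for s in sens]))
    return CrossValReport(
        classes=classes, confusion=C, accuracy=float(acc),
        adjusted_error_rate=balanced_err, raw_error_rate=float(1 - acc),
        sensitivity=float(np.nanmean(sens)), specificity=float(np.nanmean(spec)),
        per_class=pd.DataFrame(per_rows),
    )


def loocv_lda(table: pd.DataFrame, elements, group_col: str = "trend",
              **kwargs) -> CrossValReport:
    """Leave-one-out cross-validation of the discriminant.

    Each sample is classified by a model fitted without it (Gaussian
    equal-covariance posterior, priors re-estimated per fold).
    """
    data = table[[group_col, *elements]].dropna().reset_index(drop=True)
    X = data[list(elements)]
    y = data[group_col].astype(object).to_numpy()
    classes = kwargs.pop("class_order", None)
    if classes is None:
        if isinstance(data[group_col].dtype, pd.CategoricalDtype):
            classes = [c for c in data[group_col].cat.categories if c in set(y)]
        else:
            classes = sorted(pd.unique(y))
    n = len(data)
    if n < len(classes) + 2:
        raise ValueError("too few samples for leave-one-out cross-validation")
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        y_train = y[mask]
        for c in classes:
            if np.sum(y_train == c) < 2:
                raise ValueError(f"fold {i} leaves class {c!r} with <2 samples")
        est = TrendDiscriminant(class_order=classes, **kwargs)
        est.fit(X.iloc[mask], y_train)
        preds[i] = est.predict(X.iloc[[i]])[0]
    return confusion_report(y, preds, classes)


# ---------------------------------------------------------------------------
# discriminant-scale benchmarks


@dataclass
class LdBenchmarks:
    limit_ld1: float   # midpoint between declining and stable centroids
    target_ld1: float  # midpoint between stable and increasing centroids


def ld_midpoint_benchmarks(model: TrendDiscriminant,
                           lower: str = "declining", middle: str = "stable",
                           upper: str = "increasing") -> LdBenchmarks:
    """Midpoints of adjacent class centroids on the first discriminant."""
    check_is_fitted(model, "centroids_")
    pos = {c: i for i, c in enumerate(model.classes_)}
    for c in (lower, middle, upper):
        if c not in pos:
            raise ValueError(f"model has no class {c!r}")
    ld1 = {c: float(model.centroids_[pos[c], 0]) for c in (lower, middle, upper)}
    return LdBenchmarks(
        limit_ld1=(ld1[middle] + ld1[lower]) / 2.0,
        target_ld1=(ld1[middle] + ld1[upper]) / 2.0,
    )
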