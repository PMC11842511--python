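"""Discriminant stage: MANOVA vs oracles, LDA conventions, LOOCV, benchmarks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elembench import (TrendDiscriminant, fit_lda, group_summary,
                       ld_midpoint_benchmarks, loocv_lda, manova_wilks)
from elembench.discriminant import CollinearityError, confusion_report
from conftest import make_table

TRENDS = ("declining", "stable", "increasing")


def gaussian_groups(rng, centers, n_per_group, sd=1.0):
    """Sample table with one Gaussian cluster per trend class."""
    conc = {f"E{j}": [] for j in range(len(next(iter(centers.values()))))}
    trend = []
    for cls, mu in centers.items():
        X = rng.normal(mu, sd, size=(n_per_group, len(mu)))
        for j in range(X.shape[1]):
            conc[f"E{j}"].extend(X[:, j])
        trend.extend([cls] * n_per_group)
    return make_table(conc, trend=trend)


class TestGroupSummary:
    def test_mean_and_t_interval(self):
        table = make_table({"Cu": [4.0, 5.0, 6.0]})
        out = group_summary(table, ["Cu"])
        row = out.iloc[0]
        assert row["mean"] == 5.0
        # closed form: 5 +/- t(.975, 2) * 1/sqrt(3)
        half = stats.t.ppf(0.975, 2) / np.sqrt(3)
        assert row["ci_lower"] == pytest.approx(5 - half)
        assert row["ci_upper"] == pytest.approx(5 + half)
        assert row["ci_lower"] == pytest.approx(2.5159, abs=1e-4)

    def test_constant_values_zero_width(self):
        table = make_table({"Cu": [5.0, 5.0, 5.0]})
        row = group_summary(table, ["Cu"]).iloc[0]
        assert row["ci_lower"] == row["ci_upper"] == 5.0

    def test_single_observation_rejected(self):
        table = make_table({"Cu": [5.0]})
        with pytest.raises(ValueError, match="CI undefined"):
            group_summary(table, ["Cu"])


class TestManova:
    def test_single_response_equals_anova_f_by_sums_of_squares(self):
        rng = np.random.default_rng(0)
        centers = {"declining": [0.0], "stable": [0.6], "increasing": [1.1]}
        table = gaussian_groups(rng, centers, 20)
        res = manova_wilks(table, ["E0"])
        # independent oracle: explicit between/within sums of squares
        y = table["E0"].to_numpy()
        g = table["trend"].to_numpy()
        grand = y.mean()
        ssb = sum(len(y[g == c]) * (y[g == c].mean() - grand) ** 2 for c in TRENDS)
        ssw = sum(((y[g == c] - y[g == c].mean()) ** 2).sum() for c in TRENDS)
        F_oracle = (ssb / 2) / (ssw / (len(y) - 3))
        assert res.univariate["F"].iloc[0] == pytest.approx(F_oracle)
        # for p=1, Rao's approximation reduces to the same F exactly
        assert res.f_approx == pytest.approx(F_oracle)

    def test_null_case_lambda_near_one(self):
        rng = np.random.default_rng(1)
        centers = {c: [0.0, 0.0, 0.0] for c in TRENDS}
        table = gaussian_groups(rng, centers, 40)
        res = manova_wilks(table, ["E0", "E1", "E2"])
        assert res.wilks_lambda > 0.9
        assert res.p > 0.05

    def test_separated_groups_lambda_tiny(self):
        rng = np.random.default_rng(2)
        centers = {"declining": [0, 0], "stable": [10, 0], "increasing": [0, 10]}
        table = gaussian_groups(rng, centers, 30)
        res = manova_wilks(table, ["E0", "E1"])
        assert res.wilks_lambda < 0.01
        assert res.p < 1e-10

    def test_agrees_with_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(3)
        centers = {"declining": [0, 0, 0], "stable": [1, 0, .5], "increasing": [0, 1, 1]}
        table = gaussian_groups(rng, centers, 25)
        res = manova_wilks(table, ["E0", "E1", "E2"])
        sm_res = MANOVA.from_formula("E0 + E1 + E2 ~ trend", data=table).mv_test()
        tab = sm_res.results["trend"]["stat"]
        assert res.wilks_lambda == pytest.approx(tab.loc["Wilks' lambda", "Value"])
        assert res.f_approx == pytest.approx(tab.loc["Wilks' lambda", "F Value"], rel=1e-6)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(4)
        centers = {"declining": [0.0], "stable": [1.0], "increasing": [2.0]}
        table = gaussian_groups(rng, centers, 10)
        table["E1"] = 2.0 * table["E0"]
        with pytest.raises(CollinearityError):
            manova_wilks(table, ["E0", "E1"])


class TestTrendDiscriminant:
    def test_two_class_matches_fisher_closed_form(self):
        rng = np.random.default_rng(5)
        X1 = rng.normal([0, 0], [1, 2], size=(40, 2))
        X2 = rng.normal([2, 1], [1, 2], size=(40, 2))
        X = np.vstack([X1, X2])
        y = np.array(["declining"] * 40 + ["stable"] * 40, dtype=object)
        est = TrendDiscriminant(class_order=("declining", "stable")).fit(X, y)
        # oracle: pooled covariance inverse times mean difference
        S = ((X1 - X1.mean(0)).T @ (X1 - X1.mean(0))
             + (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))) / (80 - 2)
        w = np.linalg.solve(S, X2.mean(0) - X1.mean(0))
        got = est.scalings_[:, 0]
        assert abs(np.corrcoef(got, w)[0, 1]) > 1 - 1e-10  # proportional

    def test_score_within_class_covariance_is_identity(self):
        rng = np.random.default_rng(6)
        centers = {"declining": [0, 0, 0], "stable": [1, .5, 0], "increasing": [2, 0, 1]}
        table = gaussian_groups(rng, centers, 50)
        est = fit_lda(table, ["E0", "E1", "E2"])
        T = est.transform(table[["E0", "E1", "E2"]])
        y = table["trend"].to_numpy()
        pooled = np.zeros((2, 2))
        for c in TRENDS:
            D = T[y == c] - T[y == c].mean(0)
            pooled += D.T @ D
        pooled /= (len(T) - 3)
        assert np.allclose(pooled, np.eye(2), atol=1e-8)

    def test_wilks_lambda_matches_manova_det_ratio(self):
        rng = np.random.default_rng(7)
        centers = {"declining": [0, 0], "stable": [.8, .1], "increasing": [1.5, 1.0]}
        table = gaussian_groups(rng, centers, 35)
        est = fit_lda(table, ["E0", "E1"])
        res = manova_wilks(table, ["E0", "E1"])
        assert est.wilks_lambda_ == pytest.approx(res.wilks_lambda)

    def test_trace_proportions_sum_to_one_and_collinear_means_degenerate(self):
        rng = np.random.default_rng(8)
        centers = {"declining": [0, 0], "stable": [1, 1], "increasing": [2, 2]}
        table = gaussian_groups(rng, centers, 60)
        est = fit_lda(table, ["E0", "E1"])
        assert est.trace_proportion_.sum() == pytest.approx(1.0)
        assert est.trace_proportion_[0] > 0.99  # means on a line -> LD1 only
        assert (est.eigenvalues_ >= 0).all()

    def test_predictions_agree_with_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(9)
        centers = {"declining": [0, 0, 0], "stable": [1, .4, .2], "increasing": [1.8, 1.2, .5]}
        table = gaussian_groups(rng, centers, 40)
        X = table[["E0", "E1", "E2"]].to_numpy()
        y = table["trend"].astype(str).to_numpy()
        ours = fit_lda(table, ["E0", "E1", "E2"]).predict(X)
        theirs = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
        assert (ours.astype(str) == theirs).mean() == 1.0

    def test_projection_geometry(self):
        rng = np.random.default_rng(10)
        centers = {"declining": [0, 0], "stable": [1, .5], "increasing": [2, 1.5]}
        table = gaussian_groups(rng, centers, 30)
        est = fit_lda(table, ["E0", "E1"])
        # a class's element-mean vector maps onto its centroid
        for i, cls in enumerate(est.classes_):
            proj = est.transform(est.means_[[i]])
            assert np.allclose(proj, est.centroids_[i])
        # the prior-weighted grand mean maps to the origin
        assert np.allclose(est.transform(est.xbar_[None, :]), 0.0, atol=1e-10)
        # linearity: shifting one predictor moves scores by its coefficient row
        x0 = est.xbar_.copy()
        x1 = x0.copy()
        x1[0] += 1.0
        diff = est.transform(x1[None, :]) - est.transform(x0[None, :])
        assert np.allclose(diff[0], est.scalings_[0])

    def test_scores_invariant_under_predictor_rescaling(self):
        rng = np.random.default_rng(11)
        centers = {"declining": [0, 0], "stable": [1, .5], "increasing": [2, 1.5]}
        table = gaussian_groups(rng, centers, 30)
        est = fit_lda(table, ["E0", "E1"])
        scaled = table.copy()
        scaled["E0"] = scaled["E0"] * 1000.0
        est2 = fit_lda(scaled, ["E0", "E1"])
        T1 = est.transform(table[["E0", "E1"]])
        T2 = est2.transform(scaled[["E0", "E1"]])
        assert np.allclose(T1, T2, atol=1e-8)
        b1, b2 = ld_midpoint_benchmarks(est), ld_midpoint_benchmarks(est2)
        assert b1.limit_ld1 == pytest.approx(b2.limit_ld1)
        assert b1.target_ld1 == pytest.approx(b2.target_ld1)


class TestLoocv:
    def test_perfectly_separated_clusters(self):
        rng = np.random.default_rng(12)
        centers = {"declining": [0, 0], "stable": [10, 0], "increasing": [0, 10]}
        table = gaussian_groups(rng, centers, 15)
        rep = loocv_lda(table, ["E0", "E1"])
        assert rep.accuracy == 1.0
        assert rep.adjusted_error_rate == 0.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_nine_sample_confusion_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        centers = {"declining": [0.0, 0.0], "stable": [1.5, 0.5], "increasing": [3.0, 1.0]}
        table = gaussian_groups(rng, centers, 3)
        elements = ["E0", "E1"]
        rep = loocv_lda(table, elements)
        # oracle: refit from scratch for each fold and classify by the
        # Gaussian equal-covariance discriminant score computed directly
        X = table[elements].to_numpy()
        y = table["trend"].to_numpy()
        preds = []
        for i in range(9):
            mask = np.arange(9) != i
            Xt, yt = X[mask], y[mask]
            classes = list(TRENDS)
            S = np.zeros((2, 2))
            for c in classes:
                D = Xt[yt == c] - Xt[yt == c].mean(0)
                S += D.T @ D
            S /= len(Xt) - len(classes)
            Sinv = np.linalg.inv(S)
            best, best_score = None, -np.inf
            for c in classes:
                mu = Xt[yt == c].mean(0)
                pi = (yt == c).mean()
                score = X[i] @ Sinv @ mu - 0.5 * mu @ Sinv @ mu + np.log(pi)
                if score > best_score:
                    best, best_score = c, score
            preds.append(best)
        oracle = confusion_report(y, np.array(preds, dtype=object), list(TRENDS))
        assert np.array_equal(rep.confusion, oracle.confusion)

    def test_confusion_row_sums_are_class_counts(self):
        rng = np.random.default_rng(14)
        centers = {"declining": [0], "stable": [1], "increasing": [2]}
        table = gaussian_groups(rng, centers, 12)
        rep = loocv_lda(table, ["E0"])
        assert rep.confusion.sum(axis=1).tolist() == [12, 12, 12]
        assert rep.accuracy + rep.raw_error_rate == pytest.approx(1.0)

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(15)
        centers = {"declining": [0, 0], "stable": [2, 0], "increasing": [0, 2]}
        table = gaussian_groups(rng, centers, 60)
        table["trend"] = rng.permutation(table["trend"].to_numpy())
        rep = loocv_lda(table, ["E0", "E1"])
        assert 0.2 < rep.accuracy < 0.47  # chance level for 3 balanced classes


class TestLdBenchmarks:
    def test_midpoint_arithmetic(self):
        est = TrendDiscriminant(class_order=TRENDS)
        est.classes_ = np.asarray(TRENDS, dtype=object)
        est.centroids_ = np.array([[-1.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        b = ld_midpoint_benchmarks(est)
        assert b.limit_ld1 == -0.5 and b.target_ld1 == 1.0

    def test_symmetric_centroids(self):
        est = TrendDiscriminant(class_order=TRENDS)
        est.classes_ = np.asarray(TRENDS, dtype=object)
        est.centroids_ = np.array([[-2.0], [0.0], [2.0]])
        b = ld_midpoint_benchmarks(est)
        assert (b.limit_ld1, b.target_ld1) == (-1.0, 1.0)

    def test_missing_class_rejected(self):
        est = TrendDiscriminant(class_order=("declining", "stable"))
        est.classes_ = np.asarray(["declining", "stable"], dtype=object)
        est.centroids_ = np.array([[-1.0], [1.0]])
        with pytest.raises(ValueError, match="increasing"):
            ld_midpoint_benchmarks(est)
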