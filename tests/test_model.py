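"""Classifier layer: metric formulas, SVM behavior, CV schemes, ROC, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from drowsyeeg.metrics import (
    ConfusionCounts,
    auc_trapezoid,
    compute_metrics,
    confusion_from_predictions,
    roc_auc,
    roc_points,
)
from drowsyeeg.model import (
    DrowsinessClassifier,
    GridSpec,
    aggregate_probabilities,
    compare_conditions,
    drowsiness_probability,
    losocv,
    nested_cv,
    train_svm_rbf,
)

# Published evaluation counts with their printed metric rows:
# (tp, fp, fn, tn, precision, sensitivity, specificity, accuracy, f_measure),
# one entry per feature set and KSS-threshold condition.
PRINTED_RESULTS = {
    "thr5_psd_swlda": (1136, 635, 218, 402, 64.1, 83.9, 38.8, 64.3, 72.7),
    "thr5_psd_theta_alpha": (1172, 657, 182, 380, 64.1, 86.6, 36.6, 64.9, 73.6),
    "thr5_ar": (1077, 690, 277, 347, 61.0, 79.5, 33.5, 59.6, 69.0),
    "thr5_mse": (1120, 725, 234, 312, 60.7, 82.7, 30.1, 59.9, 70.0),
    "thr46_psd_swlda": (771, 361, 267, 514, 68.1, 74.3, 58.7, 67.2, 71.1),
    "thr46_psd_theta_alpha": (886, 510, 152, 365, 63.5, 85.4, 41.7, 65.4, 72.8),
    "thr46_ar": (780, 579, 258, 296, 57.4, 75.1, 33.8, 56.2, 65.1),
    "thr46_mse": (689, 507, 349, 368, 57.6, 66.4, 42.1, 55.3, 61.7),
    "thr37_psd_swlda": (477, 172, 61, 142, 73.5, 88.7, 45.2, 72.7, 80.4),
    "thr37_psd_theta_alpha": (492, 209, 46, 105, 70.2, 91.4, 33.4, 70.1, 79.4),
    "thr37_ar": (503, 245, 35, 69, 67.2, 93.5, 22.0, 67.1, 78.2),
    "thr37_mse": (461, 210, 77, 104, 68.7, 85.7, 33.1, 66.3, 76.3),
}


class TestComputeMetrics:
    @pytest.mark.parametrize("case", PRINTED_RESULTS, ids=list(PRINTED_RESULTS))
    def test_reproduces_published_metric_rows(self, case):
        tp, fp, fn, tn, prec, sens, spec, acc, fm = PRINTED_RESULTS[case]
        r = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
        assert r.precision == pytest.approx(prec, abs=0.05)
        assert r.sensitivity == pytest.approx(sens, abs=0.05)
        assert r.specificity == pytest.approx(spec, abs=0.05)
        assert r.accuracy == pytest.approx(acc, abs=0.05)
        assert r.f_measure == pytest.approx(fm, abs=0.05)

    def test_perfect_classifier_all_hundred(self):
        r = compute_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=5))
        for v in (r.precision, r.sensitivity, r.specificity, r.accuracy, r.f_measure):
            assert v == 100.0

    def test_zero_denominators_flagged_not_zero(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=4))
        assert math.isnan(r.precision) and math.isnan(r.f_measure)
        assert r.specificity == 100.0

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)
        with pytest.raises(ValueError, match="zero"):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestSVM:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-5, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.r_[np.zeros(20), np.ones(20)]
        clf = train_svm_rbf(X, y, C=1e3, gamma=0.1)
        assert (clf.predict(X) == y).all()

    def test_label_flip_flips_predictions(self, rng):
        X = rng.standard_normal((40, 2))
        y = (X[:, 0] > 0).astype(int)
        a = train_svm_rbf(X, y, C=10, gamma=1.0).predict(X)
        b = train_svm_rbf(X, 1 - y, C=10, gamma=1.0).predict(X)
        assert (a == 1 - b).all()

    def test_two_point_problem_boundary_equidistant(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array([0, 1])
        clf = train_svm_rbf(X, y, C=100, gamma=0.5)
        # midpoint lies on the boundary; the two points are symmetric
        assert clf.decision_function([[0.0, 0.0]])[0] == pytest.approx(0.0, abs=1e-9)
        d = clf.decision_function(X)
        assert abs(d[0]) == pytest.approx(abs(d[1]), abs=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_svm_rbf(rng.standard_normal((10, 2)), np.ones(10), 1.0, 1.0)


def _blob_data(rng, n=120, sep=4.0):
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 3)) + sep * y[:, None] * [1, 0.5, 0]
    return X, y


class TestNestedCV:
    def test_degenerate_grid_equals_plain_cv(self, rng):
        """A single-point grid reduces nested CV to plain stratified k-fold
        at those hyperparameters."""
        X, y = _blob_data(rng, sep=1.0)
        grid = GridSpec(c_exponents=(2,), gamma_exponents=(-3,))
        res = nested_cv(X, y, grid, outer_k=5, inner_k=3, seed=9, scale=False)
        pooled = ConfusionCounts(0, 0, 0, 0)
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=9).split(X, y):
            clf = SVC(kernel="rbf", C=2.0**2, gamma=2.0**-3).fit(X[tr], y[tr])
            pooled = pooled + confusion_from_predictions(y[te], clf.predict(X[te]))
        assert res.pooled == pooled

    def test_pooled_counts_are_fold_sums_and_partition(self, rng):
        X, y = _blob_data(rng)
        grid = GridSpec(c_exponents=(0, 5), gamma_exponents=(-5, -1))
        res = nested_cv(X, y, grid, outer_k=5, inner_k=3, seed=0)
        total = sum((f.counts for f in res.folds), ConfusionCounts(0, 0, 0, 0))
        assert total == res.pooled
        assert res.pooled.total == len(y)

    def test_grid_surface_finite_with_expected_shape(self, rng):
        X, y = _blob_data(rng)
        grid = GridSpec(c_exponents=(0, 4, 8), gamma_exponents=(-6, -2))
        res = nested_cv(X, y, grid, outer_k=4, inner_k=3, seed=1)
        assert res.grid_surface.shape == (3, 2)
        assert np.all(np.isfinite(res.grid_surface))

    def test_chosen_hyperparameters_come_from_grid(self, rng):
        X, y = _blob_data(rng)
        grid = GridSpec(c_exponents=(1, 6), gamma_exponents=(-4,))
        res = nested_cv(X, y, grid, outer_k=4, inner_k=3, seed=2)
        for f in res.folds:
            assert f.c in grid.c_values and f.gamma in grid.gamma_values

    def test_deterministic_given_seed(self, rng):
        X, y = _blob_data(rng)
        grid = GridSpec(c_exponents=(0, 5), gamma_exponents=(-5, -1))
        a = nested_cv(X, y, grid, outer_k=4, inner_k=3, seed=5)
        b = nested_cv(X, y, grid, outer_k=4, inner_k=3, seed=5)
        assert a.pooled == b.pooled
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_requires_enough_rows_per_class(self, rng):
        X = rng.standard_normal((12, 2))
        y = np.r_[np.zeros(9), np.ones(3)]
        with pytest.raises(ValueError, match="outer_k"):
            nested_cv(X, y, outer_k=10)


class TestLOSOCV:
    def test_three_subjects_three_folds(self, rng):
        X, y = _blob_data(rng, n=90)
        subjects = np.repeat(["s1", "s2", "s3"], 30)
        grid = GridSpec(c_exponents=(2,), gamma_exponents=(-2,))
        res = losocv(X, y, subjects, grid, inner_k=3, seed=0)
        assert len(res.folds) == 3

    def test_single_subject_rejected(self, rng):
        X, y = _blob_data(rng, n=30)
        with pytest.raises(ValueError, match="2 subjects"):
            losocv(X, y, np.repeat(["only"], 30))

    def test_subject_confound_inflates_windowwise_cv_only(self, rng):
        """Features carry a subject-specific offset but no class signal;
        window-level CV memorizes subjects while LOSOCV stays near chance."""
        n_sub, per = 6, 30
        subjects = np.repeat([f"s{i}" for i in range(n_sub)], per)
        y = np.repeat(np.arange(n_sub) % 2, per)
        offsets = np.repeat(rng.permutation(n_sub) * 3.0, per)
        X = offsets[:, None] + 0.3 * rng.standard_normal((n_sub * per, 2))
        grid = GridSpec(c_exponents=(4,), gamma_exponents=(-1,))
        win = nested_cv(X, y, grid, outer_k=5, inner_k=3, seed=3)
        loso = losocv(X, y, subjects, grid, inner_k=3, seed=3)
        assert win.report.accuracy > 85.0
        assert loso.report.accuracy < 65.0


class TestROC:
    def test_scores_equal_labels_auc_one(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_negated_scores_complement_auc(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(-scores, labels) == pytest.approx(1 - roc_auc(scores, labels))

    def test_independent_scores_auc_near_half(self):
        aucs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            aucs.append(roc_auc(rng.standard_normal(100), rng.integers(0, 2, 100)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_auc_equals_pairwise_ranking_oracle(self, seed):
        """AUC equals the exhaustive P(score_pos > score_neg) + 0.5 P(tie)
        over all positive/negative pairs (<= 500 rows, with ties)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.standard_normal(n), 1)  # induce ties
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points([0.1, 0.2], [1, 1])


class TestAggregation:
    @pytest.mark.parametrize(
        "preds, expected",
        [([1] * 30, 1.0), ([0] * 30, 0.0), ([1, 0, 1, 0], 0.5)],
    )
    def test_probability_is_mean_of_binary_outputs(self, preds, expected):
        assert drowsiness_probability(preds) == expected

    def test_nonbinary_predictions_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            drowsiness_probability([0.3, 0.7])

    def test_aggregate_by_recording(self):
        df = pd.DataFrame(
            {
                "recording_id": ["a"] * 4 + ["b"] * 2,
                "subject_id": ["s1"] * 4 + ["s2"] * 2,
                "prediction": [1, 1, 0, 0, 1, 1],
            }
        )
        probs = aggregate_probabilities(df)
        out = dict(zip(probs["recording_id"], probs["drowsiness_probability"]))
        assert out == {"a": 0.5, "b": 1.0}


class TestCompareConditions:
    def test_identical_lists_no_evidence(self):
        cmp = compare_conditions([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert cmp.t_stat == 0.0 and cmp.p_value == 1.0

    def test_constant_shift_with_zero_noise_is_overwhelming(self):
        a = np.array([0.8, 0.7, 0.9, 0.85])
        cmp = compare_conditions(a, a - 0.3 + 1e-12 * np.arange(4))
        assert cmp.p_value < 1e-6
        assert cmp.mean_a > cmp.mean_b

    def test_unpaired_mode_allows_unequal_sizes(self, rng):
        cmp = compare_conditions(
            rng.normal(0.8, 0.05, 10), rng.normal(0.3, 0.05, 12), paired=False
        )
        assert cmp.p_value < 1e-6

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_conditions([0.5], [0.4])


def test_classifier_fitted_attributes(rng):
    X, y = _blob_data(rng)
    grid = GridSpec(c_exponents=(0, 5), gamma_exponents=(-5, -1))
    clf = DrowsinessClassifier(grid=grid, inner_k=3).fit(pd.DataFrame(X, columns=list("abc")), y)
    assert hasattr(clf, "best_C_") and hasattr(clf, "best_gamma_")
    assert clf.grid_scores_.shape == (2, 2)
    assert set(np.unique(clf.predict(X))) <= {0, 1}
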