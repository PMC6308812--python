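"""RBF-SVM classification with nested cross-validated grid search.

The classifier is a soft-margin SVM with the Gaussian RBF kernel
K(x, x') = exp(-gamma ||x - x'||^2).  Hyperparameters (C, gamma) are
chosen by grid search over powers of two (C in 2^-2..2^11, gamma in
2^-10..2^3) maximizing inner-CV accuracy; generalization is estimated by
an outer CV whose test folds never touch scaling, feature selection or
hyperparameter choice (nested cross-validation).  Subject-level
generalization uses leave-one-subject-out outer folds (LOSOCV).

Window-level binary outputs are aggregated per recording into a
*drowsiness probability* (the mean of the 0/1 outputs), and two task
conditions are compared with a paired t-test on per-subject
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneGroupOut,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import (
    ConfusionCounts,
    MetricsReport,
    compute_metrics,
    confusion_from_predictions,
    roc_auc,
)
from .scaling import NIQRScaler
from .swlda import SWLDASelector


@dataclass(frozen=True)
class GridSpec:
    """Powers-of-two hyperparameter grid for the RBF-SVM."""

    c_exponents: tuple[int, ...] = tuple(range(-2, 12))
    gamma_exponents: tuple[int, ...] = tuple(range(-10, 4))

    def __post_init__(self) -> None:
        if not self.c_exponents or not self.gamma_exponents:
            raise ValueError("grids must be non-empty")

    @property
    def c_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(sorted(self.c_exponents), dtype=float)

    @property
    def gamma_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(sorted(self.gamma_exponents), dtype=float)

    @classmethod
    def coarse(cls, step: int = 2) -> "GridSpec":
        """Thinned grid (every ``step``-th exponent) for faster searches."""
        return cls(tuple(range(-2, 12, step)), tuple(range(-10, 4, step)))


def train_svm_rbf(X, y, C: float, gamma: float) -> SVC:
    """Fit a single RBF-SVM at fixed hyperparameters (both classes required)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    return SVC(C=C, gamma=gamma, kernel="rbf").fit(np.asarray(X, dtype=float), y)


class DrowsinessClassifier(ClassifierMixin, BaseEstimator):
    """Robust scaling -> optional SWLDA selection -> grid-searched RBF-SVM.

    ``fit`` learns the scaler and the stepwise selection on the training
    data only, then grid-searches (C, gamma) by inner stratified
    ``inner_k``-fold CV accuracy.  Ties in inner accuracy break to the
    smallest C, then the smallest gamma.

    Fitted attributes: ``best_C_``, ``best_gamma_``, ``grid_scores_``
    (len(C) x len(gamma) inner-accuracy surface), ``selected_features_``.
    """

    def __init__(
        self,
        grid: GridSpec | None = None,
        inner_k: int = 10,
        scale: bool = True,
        select: bool = False,
        p_enter: float = 0.1,
        p_remove: float = 0.15,
        random_state: int = 0,
    ):
        self.grid = grid
        self.inner_k = inner_k
        self.scale = scale
        self.select = select
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.random_state = random_state

    def fit(self, X, y):
        grid = self.grid or GridSpec()
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.classes_ = classes
        self.scaler_ = NIQRScaler() if self.scale else None
        Xt = self.scaler_.fit_transform(X) if self.scaler_ else X
        self.selector_ = None
        self.selected_features_ = names
        if self.select:
            self.selector_ = SWLDASelector(p_enter=self.p_enter, p_remove=self.p_remove)
            frame = pd.DataFrame(Xt, columns=names) if names else Xt
            self.selector_.fit(frame, y)
            Xt = self.selector_.transform(Xt)
            if names:
                self.selected_features_ = list(
                    np.asarray(names, dtype=object)[self.selector_.support_]
                )
        k = int(min(self.inner_k, counts.min()))
        if k < 2:
            raise ValueError("need at least 2 samples per class for inner CV")
        inner = StratifiedKFold(k, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            SVC(kernel="rbf"),
            param_grid={"C": list(grid.c_values), "gamma": list(grid.gamma_values)},
            scoring="accuracy",
            cv=inner,
            n_jobs=1,
        )
        search.fit(Xt, y)
        self.best_C_ = float(search.best_params_["C"])
        self.best_gamma_ = float(search.best_params_["gamma"])
        # ParameterGrid iterates C slowest (keys sorted), so the mean inner
        # accuracies reshape to a (n_C, n_gamma) surface.
        self.grid_scores_ = search.cv_results_["mean_test_score"].reshape(
            len(grid.c_values), len(grid.gamma_values)
        )
        self.svm_ = SVC(kernel="rbf", C=self.best_C_, gamma=self.best_gamma_).fit(Xt, y)
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        if self.selector_ is not None:
            X = self.selector_.transform(X)
        return X

    def predict(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict(self._transform(X))

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self._transform(X))


@dataclass
class FoldResult:
    fold: int
    c: float
    gamma: float
    counts: ConfusionCounts


@dataclass
class CVResult:
    """Per-fold choices, pooled confusion counts and metrics, grid surface."""

    folds: list[FoldResult]
    pooled: ConfusionCounts
    report: MetricsReport
    grid_surface: np.ndarray  # mean inner accuracy, shape (n_C, n_gamma)
    c_values: np.ndarray
    gamma_values: np.ndarray
    scores: np.ndarray  # pooled outer-test decision scores
    y_true: np.ndarray
    predictions: pd.DataFrame | None = None  # per-row outer-test predictions

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def auc(self) -> float | None:
        return self.report.auc


def _run_cv(X, y, splits, grid, inner_k, seed, scale, select, meta=None) -> CVResult:
    grid = grid or GridSpec()
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds, surfaces = [], []
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, (tr, te) in enumerate(splits):
        clf = DrowsinessClassifier(
            grid=grid, inner_k=inner_k, scale=scale, select=select, random_state=seed
        )
        Xtr = pd.DataFrame(Xv[tr], columns=names) if names else Xv[tr]
        clf.fit(Xtr, y[tr])
        p = clf.predict(Xv[te])
        preds[te] = p
        scores[te] = clf.decision_function(Xv[te])
        counts = confusion_from_predictions(y[te], p)
        pooled = pooled + counts
        folds.append(FoldResult(i, clf.best_C_, clf.best_gamma_, counts))
        surfaces.append(clf.grid_scores_)
    auc = roc_auc(scores, y) if len(np.unique(y)) == 2 else None
    report = compute_metrics(pooled, auc=auc)
    pred_df = None
    if meta is not None:
        pred_df = meta.copy()
        pred_df["prediction"] = preds
        pred_df["score"] = scores
    return CVResult(
        folds=folds,
        pooled=pooled,
        report=report,
        grid_surface=np.mean(surfaces, axis=0),
        c_values=grid.c_values,
        gamma_values=grid.gamma_values,
        scores=scores,
        y_true=y,
        predictions=pred_df,
    )


def nested_cv(
    X,
    y,
    grid: GridSpec | None = None,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    groups=None,
    scale: bool = True,
    select: bool = False,
    meta: pd.DataFrame | None = None,
) -> CVResult:
    """Nested stratified CV: outer folds estimate generalization, inner
    folds (on outer-train data only) choose (C, gamma).

    ``groups`` (e.g. recording ids) switches the outer folds to grouped
    stratification so windows of one recording never straddle a fold
    boundary.  Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < outer_k:
        raise ValueError(
            f"need at least outer_k={outer_k} rows per class, got {counts.min()}"
        )
    if groups is None:
        outer = StratifiedKFold(outer_k, shuffle=True, random_state=seed)
        splits = outer.split(np.zeros(len(y)), y)
    else:
        outer = StratifiedGroupKFold(outer_k, shuffle=True, random_state=seed)
        splits = outer.split(np.zeros(len(y)), y, groups=np.asarray(groups))
    return _run_cv(X, y, splits, grid, inner_k, seed, scale, select, meta)


def losocv(
    X,
    y,
    subjects,
    grid: GridSpec | None = None,
    inner_k: int = 10,
    seed: int = 0,
    scale: bool = True,
    select: bool = False,
    meta: pd.DataFrame | None = None,
) -> CVResult:
    """Leave-one-subject-out CV: each outer fold holds out one subject."""
    subjects = np.asarray(subjects)
    if len(np.unique(subjects)) < 2:
        raise ValueError("LOSOCV requires at least 2 subjects")
    splits = LeaveOneGroupOut().split(np.zeros(len(subjects)), y, groups=subjects)
    return _run_cv(X, y, splits, grid, inner_k, seed, scale, select, meta)


def drowsiness_probability(window_predictions) -> float:
    """Mean of a recording's binary window outputs: 1.0 = all drowsy."""
    p = np.asarray(window_predictions, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one window prediction")
    if not np.all(np.isin(p, [0.0, 1.0])):
        raise ValueError("window predictions must be binary 0/1")
    return float(p.mean())


def aggregate_probabilities(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-recording drowsiness probabilities from window predictions.

    Expects columns ``recording_id`` and ``prediction`` (binary); other
    metadata columns are carried through by first value.
    """
    rows = []
    for rec_id, grp in predictions.groupby("recording_id", sort=True):
        row = {"recording_id": rec_id,
               "drowsiness_probability": drowsiness_probability(grp["prediction"]),
               "n_windows": len(grp)}
        for col in ("subject_id", "session", "condition"):
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionComparison:
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    paired: bool


def compare_conditions(probs_a, probs_b, paired: bool = True) -> ConditionComparison:
    """t-test of per-subject drowsiness probabilities between conditions.

    Paired by default (every subject completed both tasks).  Identical
    paired samples are the degenerate no-evidence case and return
    t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per condition")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length conditions")
        diff = a - b
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return ConditionComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_stat=float(t), p_value=float(p), paired=paired,
    )
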