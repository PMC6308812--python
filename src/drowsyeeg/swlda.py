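"""Step-wise linear discriminant analysis (SWLDA) feature selection.

SWLDA in its standard BCI formulation is forward/backward stepwise
ordinary-least-squares regression of the 0/1 class label on the
features.  At each forward step the candidate with the smallest
partial-F p-value enters if p < p_enter (default 0.1); after every entry
any included feature whose partial-F p-value has risen above p_remove
(default 0.15) is dropped.  Selection therefore depends only on feature
distributions, not on the downstream classifier, which makes it cheap
enough to run inside every cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

# Relative rank tolerance for declaring a candidate collinear with the
# current design: the RSS improvement is numerically indistinguishable
# from zero.
_RSS_TOL = 1e-10


@dataclass(frozen=True)
class StepRecord:
    step: int
    action: str  # "add" | "remove" | "skip-collinear"
    feature: str
    p_value: float


@dataclass
class SWLDAResult:
    selected: list[str]
    step_log: list[StepRecord]
    p_enter: float = 0.1
    p_remove: float = 0.15


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the OLS fit y ~ [1, X]."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), int(rank)


def partial_f_pvalue(
    X_current: np.ndarray, candidate: np.ndarray, y: np.ndarray
) -> float:
    """p-value of the partial F-test for adding ``candidate`` to the model.

    Compares residual sums of squares of the OLS regressions of the 0/1
    label on the current features with and without the candidate, against
    an F(1, n - k - 2) reference where k is the current model size.
    Returns 1.0 when the candidate is numerically collinear with the
    current design (no RSS improvement is measurable).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X_current = np.asarray(X_current, dtype=float).reshape(n, -1)
    k = X_current.shape[1]
    dof = n - k - 2
    if dof <= 0:
        raise ValueError(f"not enough rows (n={n}) for a model of size {k + 1}")
    rss0, _ = _rss(X_current, y)
    X_full = np.column_stack([X_current, np.asarray(candidate, dtype=float)])
    rss1, rank = _rss(X_full, y)
    if rank < X_full.shape[1] + 1 and rss0 - rss1 <= _RSS_TOL * max(rss0, 1.0):
        return 1.0  # collinear candidate: no measurable improvement
    delta = max(rss0 - rss1, 0.0)
    if rss1 <= _RSS_TOL * max(rss0, 1.0):
        return 0.0  # perfect fit
    f_stat = delta / (rss1 / dof)
    return float(f_dist.sf(f_stat, 1, dof))


def swlda_select(
    X,
    y,
    feature_names: list[str] | None = None,
    p_enter: float = 0.1,
    p_remove: float = 0.15,
    max_steps: int | None = None,
) -> SWLDAResult:
    """Forward/backward stepwise selection on a binary label.

    Deterministic: candidates are examined in feature-name order and ties
    in p-value break lexically, so the result is invariant to row order.
    Terminates when a full forward+backward pass changes nothing, when a
    model state repeats, or after ``max_steps`` (default 2 * n_features).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    if len(set(np.unique(y))) < 2:
        raise ValueError("labels contain a single class; SWLDA needs both")
    if max_steps is None:
        max_steps = 2 * p
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    order = np.argsort(np.asarray(feature_names, dtype=object), kind="stable")
    cols = {name: X[:, j] for j, name in enumerate(feature_names)}
    names_sorted = [feature_names[j] for j in order]

    selected: list[str] = []
    log: list[StepRecord] = []
    seen_states = {frozenset()}
    step = 0
    while step < max_steps:
        changed = False
        # forward: best candidate by smallest p, lexical tie-break
        candidates = [nm for nm in names_sorted if nm not in selected]
        if candidates:
            cur = np.column_stack([cols[nm] for nm in selected]) if selected else np.empty((n, 0))
            pvals = [(partial_f_pvalue(cur, cols[nm], y), nm) for nm in candidates]
            best_p, best_nm = min(pvals, key=lambda t: (t[0], t[1]))
            if best_p < p_enter:
                step += 1
                selected.append(best_nm)
                log.append(StepRecord(step, "add", best_nm, best_p))
                changed = True
        # backward: drop any included feature no longer significant
        while len(selected) > 1:
            worst_p, worst_nm = -1.0, None
            for nm in sorted(selected):
                others = [o for o in selected if o != nm]
                cur = np.column_stack([cols[o] for o in others]) if others else np.empty((n, 0))
                pv = partial_f_pvalue(cur, cols[nm], y)
                if pv > worst_p:
                    worst_p, worst_nm = pv, nm
            if worst_p > p_remove:
                step += 1
                selected.remove(worst_nm)
                log.append(StepRecord(step, "remove", worst_nm, worst_p))
                changed = True
            else:
                break
        state = frozenset(selected)
        if not changed:
            break
        if state in seen_states:
            break  # cycle guard: model state repeated
        seen_states.add(state)
    return SWLDAResult(selected=selected, step_log=log, p_enter=p_enter, p_remove=p_remove)


class SWLDASelector(SelectorMixin, BaseEstimator):
    """sklearn selector wrapping :func:`swlda_select`.

    Fitted attributes: ``result_`` (the full step log) and ``support_``
    (boolean mask over input features).  Falls back to keeping all
    features when the stepwise search selects none, so that a pipeline
    never collapses to an empty design.
    """

    def __init__(self, p_enter: float = 0.1, p_remove: float = 0.15,
                 max_steps: int | None = None, keep_all_if_empty: bool = True):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_steps = max_steps
        self.keep_all_if_empty = keep_all_if_empty

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.n_features_in_ = Xv.shape[1]
        if names is None:
            names = [f"x{i:04d}" for i in range(Xv.shape[1])]
        self.input_names_ = np.asarray(names, dtype=object)
        self.result_ = swlda_select(
            Xv, y, feature_names=names,
            p_enter=self.p_enter, p_remove=self.p_remove, max_steps=self.max_steps,
        )
        mask = np.isin(self.input_names_, self.result_.selected)
        if not mask.any() and self.keep_all_if_empty:
            mask = np.ones(Xv.shape[1], dtype=bool)
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
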