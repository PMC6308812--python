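"""Robust feature scaling by median and normalized interquartile range.

Each feature is centered on its training median and divided by its NIQR,

    NIQR = (q_hi - q_lo) * 0.7413,      z = (x - median) / NIQR,

with the quantile pair (0.35, 0.65) rather than the classical quartiles —
a deliberately narrow spread estimate that further suppresses the heavy
outliers dry-electrode EEG produces.  The 0.7413 constant is the
normal-consistency factor for the 25-75 IQR and is kept verbatim with the
35/65 pair; ``consistent_constant=True`` switches to the 35/65-consistent
factor 1/(2 * Phi^-1(0.65)) for users who want an unbiased SD estimate
under normality.

Quantiles use linear interpolation of order statistics (numpy's default,
the "type 7" rule).  Features with zero quantile spread on the training
data are flagged and dropped from the transformed output with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

NIQR_CONSTANT = 0.7413


@dataclass
class RobustScalerParams:
    """Per-feature median and NIQR learned on training data."""

    feature_names: list[str]
    median: np.ndarray
    niqr: np.ndarray
    q_lo: float = 0.35
    q_hi: float = 0.65
    niqr_constant: float = NIQR_CONSTANT

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "median": [float(v) for v in self.median],
            "niqr": [float(v) for v in self.niqr],
            "q_lo": self.q_lo,
            "q_hi": self.q_hi,
            "niqr_constant": self.niqr_constant,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RobustScalerParams":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            feature_names=list(p["feature_names"]),
            median=np.asarray(p["median"], dtype=float),
            niqr=np.asarray(p["niqr"], dtype=float),
            q_lo=p["q_lo"],
            q_hi=p["q_hi"],
            niqr_constant=p["niqr_constant"],
        )


class NIQRScaler(TransformerMixin, BaseEstimator):
    """Median/NIQR robust scaler (sklearn transformer).

    Fitted attributes: ``median_``, ``niqr_`` (per feature) and
    ``zero_spread_mask_`` flagging features whose q_hi - q_lo spread is
    zero on the training data; those columns are dropped by transform.
    """

    def __init__(
        self,
        q_lo: float = 0.35,
        q_hi: float = 0.65,
        niqr_constant: float = NIQR_CONSTANT,
        consistent_constant: bool = False,
    ):
        self.q_lo = q_lo
        self.q_hi = q_hi
        self.niqr_constant = niqr_constant
        self.consistent_constant = consistent_constant

    def _constant(self) -> float:
        if self.consistent_constant:
            return float(1.0 / (norm.ppf(self.q_hi) - norm.ppf(self.q_lo)))
        return self.niqr_constant

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 3:
            raise ValueError("robust scaler needs at least 3 training rows")
        self.median_ = np.median(X, axis=0)
        spread = np.quantile(X, self.q_hi, axis=0) - np.quantile(X, self.q_lo, axis=0)
        self.niqr_ = spread * self._constant()
        self.zero_spread_mask_ = spread == 0
        self.n_features_in_ = X.shape[1]
        if self.zero_spread_mask_.any():
            warnings.warn(
                f"{int(self.zero_spread_mask_.sum())} feature(s) have zero "
                "quantile spread and will be dropped by transform",
                UserWarning,
                stacklevel=2,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        keep = ~self.zero_spread_mask_
        return (X[:, keep] - self.median_[keep]) / self.niqr_[keep]

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        return X

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "median_")
        if input_features is None:
            input_features = getattr(
                self,
                "feature_names_in_",
                np.asarray([f"x{i}" for i in range(self.n_features_in_)], dtype=object),
            )
        return np.asarray(input_features, dtype=object)[~self.zero_spread_mask_]


def fit_robust_scaler(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    q_lo: float = 0.35,
    q_hi: float = 0.65,
    niqr_constant: float = NIQR_CONSTANT,
) -> RobustScalerParams:
    """Learn per-feature median and NIQR from training rows only."""
    from .windows import feature_names as _names

    names = feature_names or _names(table)
    scaler = NIQRScaler(q_lo=q_lo, q_hi=q_hi, niqr_constant=niqr_constant)
    scaler.fit(table[names])
    return RobustScalerParams(
        feature_names=names,
        median=scaler.median_,
        niqr=scaler.niqr_,
        q_lo=q_lo,
        q_hi=q_hi,
        niqr_constant=niqr_constant,
    )


def apply_robust_scaler(table: pd.DataFrame, params: RobustScalerParams) -> pd.DataFrame:
    """z = (x - median) / NIQR per feature; zero-NIQR features dropped."""
    missing = [n for n in params.feature_names if n not in table.columns]
    if missing:
        raise ValueError(f"table lacks features {missing}")
    out = table.copy()
    drop = []
    for name, med, niqr in zip(params.feature_names, params.median, params.niqr):
        if niqr == 0:
            drop.append(name)
            continue
        out[name] = (out[name] - med) / niqr
    if drop:
        warnings.warn(f"dropping zero-NIQR features {drop}", UserWarning, stacklevel=2)
        out = out.drop(columns=drop)
    return out
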