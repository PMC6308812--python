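"""Window-level feature extractors: band power, AR coefficients, multiscale entropy.

Three families of features summarize each 10 s EEG window:

* **Band power** — a Blackman-tapered periodogram integrated over named
  half-open frequency bands.  Absolute linear power (signal-units^2) is
  the default; a Welch mode is available for variance-reduced estimates.
* **Autoregressive coefficients** — the order-5 AR parameters solved from
  the Yule-Walker equations on biased sample autocovariances.  AR models
  give better spectral resolution than the periodogram on short segments.
* **Multiscale entropy** — sample entropy (m = 2, r = 0.15 * SD) of the
  window coarse-grained at scales tau = 1..n_scales, quantifying signal
  complexity across temporal scales.

Each extractor exists as a plain function on one window and as an sklearn
transformer over an (n_windows, n_samples) array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import periodogram, welch
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import BANDS_11, Band, validate_band_set


# ---------------------------------------------------------------------------
# Band-grouped power spectral density
# ---------------------------------------------------------------------------

def compute_psd_bands(
    x: np.ndarray,
    fs: float,
    bands: list[Band] | None = None,
    method: str = "periodogram",
) -> dict[str, float]:
    """Integrated PSD per band from a Blackman-tapered spectral estimate.

    Power in band [low, high) is the rectangle-rule integral of the PSD
    over frequency bins with low <= f < high.  Multiplying the signal by
    c multiplies every band power by c^2.
    """
    bands = BANDS_11 if bands is None else bands
    validate_band_set(bands)
    x = np.asarray(x, dtype=float)
    if method == "periodogram":
        f, p = periodogram(x, fs=fs, window="blackman")
    elif method == "welch":
        nper = min(x.size, int(2 * fs))
        f, p = welch(x, fs=fs, window="blackman", nperseg=nper)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    df = f[1] - f[0]
    out = {}
    for band in bands:
        sel = (f >= band.low) & (f < band.high)
        out[band.name] = float(p[sel].sum() * df)
    return out


# ---------------------------------------------------------------------------
# Yule-Walker autoregressive coefficients
# ---------------------------------------------------------------------------

def autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariances r(0..max_lag) of the demeaned series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    return np.array([np.dot(x[: n - k], x[k:]) / n for k in range(max_lag + 1)])


def ar_from_autocov(r: np.ndarray, order: int) -> np.ndarray:
    """Solve the Yule-Walker system R a = r for the AR coefficients.

    ``r`` holds autocovariances r(0)..r(order); the returned ``a`` satisfy
    x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t.  Exact for an exact
    autocovariance sequence of a stable AR(p) process.
    """
    r = np.asarray(r, dtype=float)
    if r.size < order + 1:
        raise ValueError(f"need {order + 1} autocovariances, got {r.size}")
    if r[0] <= 0:
        raise ValueError("zero-variance series: Yule-Walker system is singular")
    return solve_toeplitz(r[:order], r[1 : order + 1])


def compute_ar_coeffs(x: np.ndarray, order: int = 5) -> np.ndarray:
    """Order-p Yule-Walker AR coefficients of one window."""
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        raise ValueError(f"need more than {order} samples, got {x.size}")
    r = autocovariance(x, order)
    return ar_from_autocov(r, order)


# ---------------------------------------------------------------------------
# Sample entropy and multiscale entropy
# ---------------------------------------------------------------------------

def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of consecutive ``scale``-sample blocks."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < scale:
        raise ValueError(f"series of {x.size} points is shorter than scale {scale}")
    n = (x.size // scale) * scale
    return x[:n].reshape(-1, scale).mean(axis=1)


def _template_pairs(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Count unordered template pairs (i < j) of length ``m`` within
    Chebyshev distance r.  Templates are the first ``n_templates``
    delay embeddings so counts at m and m+1 share an index set."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tree = cKDTree(emb)
    # count_neighbors counts ordered pairs including self-pairs
    total = tree.count_neighbors(tree, r, p=np.inf)
    return int((total - n_templates) // 2)


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, r_factor: float = 0.15
) -> float:
    """Sample entropy: -ln(A/B) of template-match counts at lengths m+1 and m.

    Matches use the Chebyshev distance with tolerance ``r`` (default
    ``r_factor`` times the series SD); self-matches are excluded.  Returns
    NaN (undefined) for zero-variance input or when no match extends to
    length m+1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} points, got {x.size}")
    sd = x.std()
    if r is None:
        if sd == 0:
            return float("nan")
        r = r_factor * sd
    if r <= 0 or sd == 0:
        return float("nan")
    n_templates = x.size - m
    b = _template_pairs(x, m, r, n_templates)
    if b == 0:
        return float("nan")
    a = _template_pairs(x, m + 1, r, n_templates)
    if a == 0:
        return float("nan")
    return float(-math.log(a / b))


def compute_mse(
    x: np.ndarray,
    m: int = 2,
    r_factor: float = 0.15,
    n_scales: int = 20,
    r_mode: str = "fixed",
) -> np.ndarray:
    """Sample entropy of the coarse-grained window at scales 1..n_scales.

    ``r_mode="fixed"`` (the standard definition) computes the tolerance
    once from the scale-1 SD; ``"per-scale"`` recomputes it per scale.
    Requires the coarsest scale to retain at least 10*(m+1) points.
    """
    x = np.asarray(x, dtype=float)
    if r_mode not in ("fixed", "per-scale"):
        raise ValueError("r_mode must be 'fixed' or 'per-scale'")
    if x.size // n_scales < 10 * (m + 1):
        raise ValueError(
            f"window of {x.size} points leaves fewer than {10 * (m + 1)} points "
            f"at scale {n_scales}; shorten n_scales or lengthen the window"
        )
    sd = x.std()
    r = r_factor * sd if sd > 0 else None
    out = np.empty(n_scales)
    for i, tau in enumerate(range(1, n_scales + 1)):
        cg = coarse_grain(x, tau)
        if r_mode == "fixed":
            out[i] = sample_entropy(cg, m=m, r=r) if r is not None else float("nan")
        else:
            out[i] = sample_entropy(cg, m=m, r_factor=r_factor)
    return out


# ---------------------------------------------------------------------------
# sklearn transformers over (n_windows, n_samples) arrays
# ---------------------------------------------------------------------------

class _WindowTransformer(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class PSDBandPower(_WindowTransformer):
    """Band-power features: one column per band of ``bands``."""

    def __init__(self, fs: float = 512.0, bands: list[Band] | None = None,
                 method: str = "periodogram"):
        self.fs = fs
        self.bands = bands
        self.method = method

    def _bands(self) -> list[Band]:
        return BANDS_11 if self.bands is None else list(self.bands)

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        bands = self._bands()
        out = np.empty((X.shape[0], len(bands)))
        for i, row in enumerate(X):
            powers = compute_psd_bands(row, self.fs, bands, method=self.method)
            out[i] = [powers[b.name] for b in bands]
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray([b.name for b in self._bands()], dtype=object)


class ARCoefficients(_WindowTransformer):
    """Yule-Walker AR(p) coefficients, default order 5."""

    def __init__(self, order: int = 5):
        self.order = order

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.order))
        for i, row in enumerate(X):
            out[i] = compute_ar_coeffs(row, self.order)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"ar_{k}" for k in range(1, self.order + 1)], dtype=object)


class MultiscaleEntropy(_WindowTransformer):
    """Per-scale sample entropy features (m = 2, r = 0.15 * SD by default)."""

    def __init__(self, m: int = 2, r_factor: float = 0.15, n_scales: int = 20,
                 r_mode: str = "fixed"):
        self.m = m
        self.r_factor = r_factor
        self.n_scales = n_scales
        self.r_mode = r_mode

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.n_scales))
        for i, row in enumerate(X):
            out[i] = compute_mse(row, self.m, self.r_factor, self.n_scales, self.r_mode)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            [f"mse_scale_{t}" for t in range(1, self.n_scales + 1)], dtype=object
        )


FEATURE_EXTRACTORS = {
    "psd": PSDBandPower,
    "ar": ARCoefficients,
    "mse": MultiscaleEntropy,
}
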