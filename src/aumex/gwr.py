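"""Geographically weighted regression (GWR) for surface validation.

A single-predictor GWR: at every sample location a weighted least-squares
line of observed concentration on modeled exposure is fitted, with weights
from an adaptive bisquare kernel (bandwidth = distance to the k-th nearest
sample). The global R^2 of the locally fitted values, 1 - RSS/TSS, is the
accuracy statistic. The adaptive neighbour count is chosen by minimizing the
corrected Akaike information criterion (AICc) with a golden-section search.

The implementation is fully vectorized: for n samples it builds the n x n
kernel matrix and solves all local 2 x 2 normal equations at once, which
keeps repeated-subset validation with hundreds of refits tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["GWRResult", "DegenerateFitError", "gwr_fit", "ols_r2"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


class DegenerateFitError(ValueError):
    """Raised when the predictor carries no variance (no fit is possible)."""


@dataclass
class GWRResult:
    global_r2: float
    bandwidth: int  # adaptive: number of nearest neighbours
    intercepts: np.ndarray
    slopes: np.ndarray
    fitted: np.ndarray
    aicc: float


def _bisquare_weights(d: np.ndarray, k: int) -> np.ndarray:
    """Adaptive bisquare kernel row-wise: bandwidth = k-th nearest distance."""
    h = np.partition(d, k - 1, axis=1)[:, k - 1]
    h = np.maximum(h, 1e-12)[:, None]
    u = d / h
    w = (1.0 - u**2) ** 2
    w[u >= 1.0] = 0.0
    return w


def _solve_local(w: np.ndarray, x: np.ndarray, y: np.ndarray):
    """All local WLS fits of y ~ 1 + x at once from the kernel matrix w."""
    s0 = w.sum(axis=1)
    s1 = w @ x
    s2 = w @ (x * x)
    t0 = w @ y
    t1 = w @ (x * y)
    det = s0 * s2 - s1 * s1
    scale = np.maximum(s0 * np.maximum(s2, 1e-300), 1e-300)
    ok = det > 1e-12 * scale
    b1 = np.where(ok, (s0 * t1 - s1 * t0) / np.where(ok, det, 1.0), 0.0)
    b0 = np.where(ok, (s2 * t0 - s1 * t1) / np.where(ok, det, 1.0), t0 / s0)
    fitted = b0 + b1 * x
    # hat diagonal: w_ii * x_i' (X'WX)^-1 x_i with w_ii = 1 at zero distance
    quad = s2 - 2.0 * s1 * x + s0 * x * x
    s_ii = np.where(ok, quad / np.where(ok, det, 1.0), 1.0 / s0)
    return b0, b1, fitted, s_ii


def _fit_at_k(d, x, y, k):
    w = _bisquare_weights(d, k)
    b0, b1, fitted, s_ii = _solve_local(w, x, y)
    n = len(y)
    rss = float(np.sum((y - fitted) ** 2))
    tr_s = float(np.sum(s_ii))
    sigma2 = max(rss / n, 1e-300)
    denom = n - 2.0 - tr_s
    if denom <= 0:
        aicc = np.inf
    else:
        aicc = n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + tr_s) / denom
    return b0, b1, fitted, rss, tr_s, aicc


def gwr_fit(
    coords: np.ndarray,
    predictor: np.ndarray,
    response: np.ndarray,
    bandwidth: int | None = None,
    min_bandwidth: int = 20,
) -> GWRResult:
    """Fit GWR of response on a single predictor over sample locations.

    ``bandwidth`` is the adaptive neighbour count; when None it is selected
    by golden-section search on AICc between ``min_bandwidth`` and n.
    """
    coords = np.asarray(coords, dtype=float)
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("GWR requires at least 30 samples")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor: GWR fit is undefined")
    d = cdist(coords, coords)

    if bandwidth is None:
        bandwidth = _select_bandwidth(d, x, y, lo=min(min_bandwidth, n), hi=n)
    bandwidth = int(np.clip(bandwidth, 3, n))

    b0, b1, fitted, rss, _, aicc = _fit_at_k(d, x, y, bandwidth)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return GWRResult(
        global_r2=float(np.clip(r2, 0.0, 1.0)),
        bandwidth=bandwidth,
        intercepts=b0,
        slopes=b1,
        fitted=fitted,
        aicc=float(aicc),
    )


def _select_bandwidth(d, x, y, lo: int, hi: int) -> int:
    """Golden-section search over the adaptive neighbour count, minimizing AICc."""
    cache: dict[int, float] = {}

    def score(k: int) -> float:
        k = int(round(k))
        if k not in cache:
            cache[k] = _fit_at_k(d, x, y, k)[5]
        return cache[k]

    a, b = float(lo), float(hi)
    c = b - _GOLDEN * (b - a)
    e = a + _GOLDEN * (b - a)
    while b - a > 2.0:
        if score(c) < score(e):
            b, e = e, c
            c = b - _GOLDEN * (b - a)
        else:
            a, c = c, e
            e = a + _GOLDEN * (b - a)
    ks = set(cache) | {int(round((a + b) / 2))}
    return min(ks, key=score)


def ols_r2(predictor: np.ndarray, response: np.ndarray) -> float:
    """Ordinary least squares R^2 of response on a single predictor."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")
    b1, b0 = np.polyfit(x, y, 1)
    resid = y - (b0 + b1 * x)
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / tss) if tss > 0 else 0.0
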