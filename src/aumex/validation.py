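"""Evaluation battery for the exposure surfaces.

Implements the full validation design of the source-comparison experiment:
GWR accuracy against held-out concentration samples, repeated random-subset
validation summarized as descriptive statistics, k-fold cross-validation with
per-fold weight refitting, one-way ANOVA comparison of surfaces, and a
multi-radius scale-variability test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fuzzy import ExposureSurface, WeightVector, rf_weights, weighted_linear_combination, ForestSettings
from .gwr import DegenerateFitError, gwr_fit
from .raster import Raster

__all__ = [
    "ValidationSummary",
    "repeated_subset_validation",
    "kfold_cv",
    "anova_surfaces",
    "scale_test",
    "KFoldResult",
]

DEFAULT_RADII_KM = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0)


def _surface_raster(surface: ExposureSurface | Raster) -> Raster:
    return surface.raster if isinstance(surface, ExposureSurface) else surface


@dataclass
class ValidationSummary:
    """Descriptive statistics of R^2 over repeated validation runs."""

    mean: float
    sd: float
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    r2_values: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_r2(cls, r2: np.ndarray) -> "ValidationSummary":
        r2 = np.asarray(r2, dtype=float)
        return cls(
            mean=float(r2.mean()),
            sd=float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
            minimum=float(r2.min()),
            q25=float(np.quantile(r2, 0.25)),
            median=float(np.quantile(r2, 0.5)),
            q75=float(np.quantile(r2, 0.75)),
            maximum=float(r2.max()),
            r2_values=r2,
        )

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "mean": self.mean,
                "sd": self.sd,
                "min": self.minimum,
                "q25": self.q25,
                "median": self.median,
                "q75": self.q75,
                "max": self.maximum,
            }
        )


def repeated_subset_validation(
    coords: np.ndarray,
    concentrations: np.ndarray,
    surface: ExposureSurface | Raster,
    n_subset: int = 3500,
    reps: int = 999,
    seed: int = 0,
    bandwidth: int | None = None,
) -> ValidationSummary:
    """GWR R^2 over repeated uniform random subsets, with descriptive statistics.

    The adaptive bandwidth is selected once by AICc on the first subset and
    held fixed across repetitions so every repetition measures sampling
    variability of the fit, not of the bandwidth search.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    n = len(y)
    if n_subset > n:
        raise ValueError(f"n_subset={n_subset} exceeds available samples ({n})")
    raster = _surface_raster(surface)
    pred = raster.sample(coords[:, 0], coords[:, 1])
    rng = np.random.default_rng(seed)
    r2 = np.empty(reps)
    for i in range(reps):
        idx = rng.choice(n, size=n_subset, replace=False)
        res = gwr_fit(coords[idx], pred[idx], y[idx], bandwidth=bandwidth)
        if bandwidth is None:
            bandwidth = res.bandwidth
        r2[i] = res.global_r2
    return ValidationSummary.from_r2(r2)


@dataclass
class KFoldResult:
    fold: int
    weights: WeightVector
    surface: ExposureSurface
    r2: float
    test_indices: np.ndarray


def kfold_cv(
    coords: np.ndarray,
    concentrations: np.ndarray,
    fuzzy_stack: list[Raster],
    k: int = 10,
    n_train: int = 3500,
    n_test: int = 750,
    seed: int = 0,
    forest: ForestSettings = ForestSettings(),
    combination: str = "",
    bandwidth: int | None = None,
) -> list[KFoldResult]:
    """k-fold cross-validation with per-fold weight refitting.

    The samples are split into k mutually disjoint test subsets of size
    ``n_test``; for each fold, RF weights are fitted on ``n_train`` samples
    drawn from outside the fold's test subset, a fresh exposure surface is
    combined, and its GWR R^2 on the held-out test subset is recorded.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k * n_test > n:
        raise ValueError(f"cannot carve {k} disjoint test subsets of {n_test} from {n}")
    if n_train > n - n_test:
        raise ValueError("n_train exceeds samples outside a test fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    features = np.column_stack(
        [layer.sample(coords[:, 0], coords[:, 1]) for layer in fuzzy_stack]
    )
    results: list[KFoldResult] = []
    for fold in range(k):
        test_idx = perm[fold * n_test : (fold + 1) * n_test]
        pool = np.setdiff1d(perm, test_idx, assume_unique=True)
        train_idx = rng.choice(pool, size=n_train, replace=False)
        if np.intersect1d(train_idx, test_idx).size:
            raise RuntimeError("internal error: train/test overlap within a fold")
        w = rf_weights(
            y[train_idx], features[train_idx],
            n_train=n_train, settings=forest, seed=int(rng.integers(2**31 - 1)),
        )
        surf = weighted_linear_combination(fuzzy_stack, w, combination=combination)
        pred = surf.raster.sample(coords[test_idx, 0], coords[test_idx, 1])
        res = gwr_fit(coords[test_idx], pred, y[test_idx], bandwidth=bandwidth)
        if bandwidth is None:
            bandwidth = res.bandwidth
        results.append(
            KFoldResult(fold=fold, weights=w, surface=surf, r2=res.global_r2,
                        test_indices=test_idx)
        )
    return results


def anova_surfaces(
    surfaces: list[ExposureSurface | Raster],
    n_sample: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way ANOVA comparing exposure surfaces at common random cells.

    The same ``n_sample`` random valid cell locations are sampled from every
    surface; values are log2-transformed (right-skew correction), with
    zero/negative cells offset by the smallest positive sampled value.
    Returns (F, p); identical groups give F = 0.
    """
    if len(surfaces) < 2:
        raise ValueError("at least two surfaces required")
    rasters = [_surface_raster(s) for s in surfaces]
    ref = rasters[0]
    valid = np.flatnonzero(ref.mask.ravel())
    rng = np.random.default_rng(seed)
    cells = rng.choice(valid, size=min(n_sample, len(valid)), replace=False)
    groups = [r.values.ravel()[cells] for r in rasters]
    stacked = np.concatenate(groups)
    positive = stacked[stacked > 0]
    if positive.size == 0:
        raise ValueError("all sampled values are non-positive; cannot log-transform")
    offset = positive.min()
    groups = [np.log2(np.where(g > 0, g, g + offset)) for g in groups]
    if all(np.array_equal(groups[0], g) for g in groups[1:]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(max(f, 0.0)), float(p)


def scale_test(
    coords: np.ndarray,
    concentrations: np.ndarray,
    surface: ExposureSurface | Raster,
    n_sites: int = 99,
    radii_km: tuple[float, ...] = DEFAULT_RADII_KM,
    min_samples: int = 30,
    seed: int = 0,
    bandwidth: int | None = None,
) -> pd.DataFrame:
    """Mean and sd of GWR R^2 within growing radii of random test sites.

    For each of ``n_sites`` random sites and each radius, a GWR is fitted on
    the samples within that distance of the site; site/radius pairs with fewer
    than ``min_samples`` local observations are flagged missing and excluded
    from the aggregation. One row per radius is always returned.
    """
    radii = list(radii_km)
    if any(r <= 0 for r in radii) or sorted(radii) != radii:
        raise ValueError("radii must be positive and ascending")
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    raster = _surface_raster(surface)
    pred = raster.sample(coords[:, 0], coords[:, 1])
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = raster.grid.extent
    sites = np.column_stack(
        [rng.uniform(xmin, xmax, n_sites), rng.uniform(ymin, ymax, n_sites)]
    )
    rows = []
    any_valid = False
    for radius in radii:
        r2s = []
        skipped = 0
        for sx, sy in sites:
            within = np.hypot(coords[:, 0] - sx, coords[:, 1] - sy) <= radius * 1000.0
            if within.sum() < max(min_samples, 30):
                skipped += 1
                continue
            try:
                res = gwr_fit(coords[within], pred[within], y[within], bandwidth=bandwidth)
            except DegenerateFitError:
                skipped += 1
                continue
            if bandwidth is None:
                bandwidth = res.bandwidth
            r2s.append(res.global_r2)
        if r2s:
            any_valid = True
        rows.append(
            {
                "radius_km": radius,
                "mean_r2": float(np.mean(r2s)) if r2s else np.nan,
                "sd_r2": float(np.std(r2s, ddof=1)) if len(r2s) > 1 else (0.0 if r2s else np.nan),
                "n_sites": len(r2s),
                "n_skipped": skipped,
            }
        )
    if not any_valid:
        raise ValueError("no radius produced any valid site; increase sample density")
    return pd.DataFrame(rows)
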