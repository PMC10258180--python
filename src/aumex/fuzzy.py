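"""Fuzzy standardization, random-forest criterion weighting, and the overlay.

Each raw criterion is mapped into a [0, 1] degree of exposure contribution by
a monotone fuzzy membership function (the classic GIS suitability-mapping
families Large / Small / MS Large / MS Small). Criterion weights are derived
from impurity-based variable importances of a random-forest regression of
observed concentrations on the fuzzified criteria, and the exposure-potential
surface is their weighted linear combination (WLC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .raster import Raster, check_aligned

__all__ = [
    "FuzzyParams",
    "WeightVector",
    "ExposureSurface",
    "fuzzy_standardize",
    "default_fuzzy_params",
    "rf_weights",
    "weighted_linear_combination",
]

FUZZY_FUNCTIONS = ("Large", "Small", "MSLarge", "MSSmall")


@dataclass(frozen=True)
class FuzzyParams:
    """Parameters of one membership function.

    Large/Small are sigmoids around ``midpoint`` (membership 0.5 there) with
    steepness ``spread``. The MS variants are parameter-free apart from the
    multipliers ``a`` (on the layer mean) and ``b`` (on the layer standard
    deviation), from which the transition is derived.
    """

    function: str
    midpoint: float | None = None  # Large/Small; None = layer median
    spread: float = 5.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.function not in FUZZY_FUNCTIONS:
            raise ValueError(f"unknown fuzzy function {self.function!r}")
        if self.spread <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("spread, a and b must be positive")


def _resolve_midpoint(x: np.ndarray, params: FuzzyParams) -> float:
    if params.midpoint is not None:
        if params.midpoint <= 0:
            raise ValueError("Large/Small midpoint must be positive")
        return params.midpoint
    pos = x[x > 0]
    mid = float(np.median(pos)) if pos.size else float(np.mean(x))
    if mid <= 0:
        raise ValueError("cannot derive a positive midpoint from the layer")
    return mid


def fuzzy_membership(x: np.ndarray, params: FuzzyParams,
                     mean: float | None = None, sd: float | None = None) -> np.ndarray:
    """Apply one membership function elementwise; output in [0, 1].

    For Large/Small, non-positive inputs take the limiting membership
    (0 for Large, 1 for Small), so layers with zero cells are well defined.
    """
    x = np.asarray(x, dtype=float)
    fn = params.function
    if fn in ("Large", "Small"):
        mid = _resolve_midpoint(x, params)
        out = np.empty_like(x)
        pos = x > 0
        ratio = np.power(x[pos] / mid, params.spread)
        if fn == "Large":
            out[pos] = ratio / (1.0 + ratio)  # = 1/(1+(x/mid)^-spread)
            out[~pos] = 0.0
        else:
            out[pos] = 1.0 / (1.0 + ratio)
            out[~pos] = 1.0
        return out
    mean = float(np.mean(x)) if mean is None else mean
    sd = float(np.std(x)) if sd is None else sd
    if sd <= 0:
        raise ValueError("MS membership requires positive layer standard deviation")
    lo = params.a * mean
    bs = params.b * sd
    above = x > lo
    denom = np.where(above, x - lo + bs, 1.0)
    if fn == "MSLarge":
        out = np.where(above, 1.0 - bs / denom, 0.0)
    else:  # MSSmall
        out = np.where(above, bs / denom, 1.0)
    return out


def fuzzy_standardize(raster: Raster, params: FuzzyParams) -> Raster:
    """Standardize a criteria raster into [0, 1] membership."""
    vals = raster.values
    m = raster.mask
    out = np.full(raster.grid.shape, raster.nodata)
    out[m] = fuzzy_membership(
        vals[m], params, mean=float(vals[m].mean()), sd=float(vals[m].std())
    )
    return raster.with_values(out)


def default_fuzzy_params() -> dict[int, FuzzyParams]:
    """Default membership assignment for the eight criteria layers.

    Proximity-style drivers increase exposure (Large / MS Large); distance and
    vegetation decrease it (Small / MS Small); the ordinal landform code 1-6
    enters Small so valleys (low codes, deposition zones) get top membership.
    """
    return {
        1: FuzzyParams("MSLarge"),   # AUM proximity
        2: FuzzyParams("Small"),     # downslope drainage distance-decay value
        3: FuzzyParams("Large"),     # wind index
        4: FuzzyParams("MSLarge"),   # topographic wind exposure
        5: FuzzyParams("Small"),     # landform class code
        6: FuzzyParams("MSSmall"),   # road distance
        7: FuzzyParams("Large"),     # groundwater hazard IDW
        8: FuzzyParams("Small"),     # NDVI
    }


@dataclass
class WeightVector:
    """Nonnegative criterion weights summing to one."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"weights must sum to 1 (got {total})")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ExposureSurface:
    """Dimensionless exposure potential in [0, 1], with provenance."""

    raster: Raster
    combination: str = ""
    weights: WeightVector | None = None


@dataclass(frozen=True)
class ForestSettings:
    """Random-forest regressor settings (standardized defaults, config-exposed)."""

    n_trees: int = 500
    max_depth: int | None = None
    min_samples_leaf: int = 1


def rf_weights(
    concentrations: np.ndarray,
    features: np.ndarray,
    n_train: int = 750,
    settings: ForestSettings = ForestSettings(),
    seed: int = 0,
) -> WeightVector:
    """Criterion weights from random-forest impurity importances.

    Fits a random-forest regressor of concentration on the fuzzified criteria
    values sampled at the training locations, then normalizes the Gini
    (variance-impurity) importances to sum to one. A random subset of
    ``n_train`` samples is used when more are supplied.
    """
    y = np.asarray(concentrations, dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n_samples, n_criteria) matching targets")
    if len(y) < n_train:
        raise ValueError(f"need at least n_train={n_train} samples, got {len(y)}")
    if np.ptp(y) == 0:
        raise ValueError("constant target: no split gain, weights undefined")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(y), size=n_train, replace=False)
    forest = RandomForestRegressor(
        n_estimators=settings.n_trees,
        max_depth=settings.max_depth,
        min_samples_leaf=settings.min_samples_leaf,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X[idx], y[idx])
    imp = forest.feature_importances_
    total = imp.sum()
    if total <= 0:  # all-constant features
        return WeightVector(np.full(X.shape[1], 1.0 / X.shape[1]))
    return WeightVector(imp / total)


def weighted_linear_combination(
    fuzzy_stack: list[Raster],
    weights: WeightVector,
    combination: str = "",
) -> ExposureSurface:
    """Convex combination of fuzzified layers: the exposure-potential surface."""
    if len(fuzzy_stack) != len(weights):
        raise ValueError("one weight per layer required")
    check_aligned(*fuzzy_stack, names=[f"layer {i+1}" for i in range(len(fuzzy_stack))])
    out = np.zeros(fuzzy_stack[0].grid.shape)
    for w, layer in zip(weights.weights, fuzzy_stack):
        out += w * layer.values
    return ExposureSurface(
        raster=Raster(fuzzy_stack[0].grid, out),
        combination=combination,
        weights=weights,
    )
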