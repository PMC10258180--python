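"""Synthetic study-area generator.

Every input the real analysis would obtain from external sources — terrain,
clustered mine point sources, a spatially varying "truth" wind field, MET
observation sources of both kinds (sparse exact stations and a smoothed,
biased regular lattice emulating gridded reanalysis), ancillary wells, roads
and vegetation, and validation samples whose concentrations are a noisy
monotone function of a known-weight exposure surface — is generated here as a
pure function of (parameters, seed), so the full pipeline is testable offline
and supports parameter-recovery experiments against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .fuzzy import WeightVector
from .met import MetPoint, MetSource
from .raster import Grid, Raster

__all__ = [
    "ValidationSample",
    "WorldTruth",
    "generate_terrain",
    "generate_mines",
    "generate_wind_truth",
    "emulate_met_sources",
    "generate_ancillary",
    "generate_validation_samples",
]


@dataclass(frozen=True)
class ValidationSample:
    """A point observation of a right-skewed concentration (ppm-like)."""

    x: float
    y: float
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")


@dataclass
class WorldTruth:
    """Ground truth behind a synthetic world, for parameter-recovery tests."""

    true_weights: np.ndarray
    wind_direction: Raster
    wind_speed: Raster
    noise_sd: float

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("true weights must be nonnegative and sum to 1")
        self.true_weights = w


def _standardized_grf(shape: tuple[int, int], sigma_cells: float, rng) -> np.ndarray:
    """Gaussian random field smoothed to the given correlation scale,
    standardized to zero mean / unit sd over the domain."""
    field = rng.standard_normal(shape)
    if sigma_cells > 0:
        field = gaussian_filter(field, sigma=sigma_cells, mode="reflect")
    sd = field.std()
    if sd == 0:
        return np.zeros(shape)
    return (field - field.mean()) / sd


def generate_terrain(grid: Grid, roughness: float, relief: float, seed: int) -> Raster:
    """Fractal terrain by spectral synthesis of fractional Brownian noise.

    White Gaussian noise is filtered in the Fourier domain with amplitude
    ~ k^-(1 + roughness) (higher roughness = steeper spectral slope = smoother
    large-scale relief), then rescaled to [0, relief].
    """
    if not 0 < roughness < 2:
        raise ValueError("roughness must lie in (0, 2)")
    if relief <= 0:
        raise ValueError("relief must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    spectrum = np.fft.fft2(white)
    ky = np.fft.fftfreq(grid.n_rows)[:, None]
    kx = np.fft.fftfreq(grid.n_cols)[None, :]
    k = np.hypot(kx, ky)
    k[0, 0] = np.inf  # zero out the DC component
    spectrum *= k ** (-(1.0 + roughness))
    field = np.real(np.fft.ifft2(spectrum))
    lo, hi = field.min(), field.max()
    values = (field - lo) / (hi - lo) * relief
    return Raster(grid, values)


def generate_mines(
    grid: Grid,
    n_clusters: int,
    mines_per_cluster: int,
    cluster_sd: float,
    area_range: tuple[float, float],
    seed: int,
) -> list:
    """Clustered mine point sources (Poisson-cluster pattern) with areas.

    Cluster parents are uniform over the grid; offspring are displaced by
    isotropic Gaussian offsets of scale ``cluster_sd``. Surface areas are
    drawn log-uniformly within ``area_range`` (m^2).
    """
    from .criteria import SourcePoint

    if n_clusters < 1 or mines_per_cluster < 1:
        raise ValueError("counts must be at least 1")
    lo, hi = area_range
    if lo <= 0 or hi < lo:
        raise ValueError("area_range must be positive and ascending")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    parents = np.column_stack(
        [rng.uniform(xmin, xmax, n_clusters), rng.uniform(ymin, ymax, n_clusters)]
    )
    mines = []
    i = 0
    for px, py in parents:
        for _ in range(mines_per_cluster):
            x = float(np.clip(px + rng.normal(0, cluster_sd), xmin, xmax))
            y = float(np.clip(py + rng.normal(0, cluster_sd), ymin, ymax))
            area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            mines.append(SourcePoint(id=f"AUM{i:03d}", x=x, y=y, area=area))
            i += 1
    return mines


def generate_wind_truth(
    grid: Grid,
    prevailing_deg: float,
    direction_sd: float,
    speed_mean: float,
    speed_sd: float,
    correlation_length: float,
    seed: int,
) -> tuple[Raster, Raster]:
    """Smooth truth fields of prevailing direction and mean speed.

    Directions are a wrapped Gaussian random field around ``prevailing_deg``
    (blowing-from convention); speeds are an independent field around
    ``speed_mean`` clipped at zero. The fields are standardized over the
    domain, so the domain-wide circular mean direction equals the prevailing
    direction up to wrapping effects.
    """
    if speed_mean <= 0:
        raise ValueError("speed_mean must be positive")
    if direction_sd < 0 or speed_sd < 0:
        raise ValueError("spreads must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma_cells = correlation_length / grid.cell_size
    f_dir = _standardized_grf(grid.shape, sigma_cells, rng)
    f_spd = _standardized_grf(grid.shape, sigma_cells, rng)
    direction = (prevailing_deg + direction_sd * f_dir) % 360.0
    speed = np.clip(speed_mean + speed_sd * f_spd, 0.0, None)
    return Raster(grid, direction), Raster(grid, speed)


def _stratified_cells(n_rows: int, n_cols: int, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Jittered stratified cell sample: one random cell in each of n blocks."""
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    n_bx = int(np.ceil(np.sqrt(n * n_cols / n_rows)))
    n_by = int(np.ceil(n / n_bx))
    blocks = [(by, bx) for by in range(n_by) for bx in range(n_bx)]
    chosen = [blocks[i] for i in rng.permutation(len(blocks))[:n]]
    rows, cols = [], []
    for by, bx in chosen:
        r0, r1 = (n_rows * by) // n_by, (n_rows * (by + 1)) // n_by
        c0, c1 = (n_cols * bx) // n_bx, (n_cols * (bx + 1)) // n_bx
        rows.append(int(rng.integers(r0, max(r1, r0 + 1))))
        cols.append(int(rng.integers(c0, max(c1, c0 + 1))))
    return np.array(rows), np.array(cols)


def _smooth_direction(direction: np.ndarray, sigma_cells: float) -> np.ndarray:
    """Smooth angular data via its unit-vector components (wrap-safe)."""
    if sigma_cells <= 0:
        return direction.copy()
    rad = np.radians(direction)
    s = gaussian_filter(np.sin(rad), sigma=sigma_cells, mode="reflect")
    c = gaussian_filter(np.cos(rad), sigma=sigma_cells, mode="reflect")
    return np.degrees(np.arctan2(s, c)) % 360.0


def emulate_met_sources(
    wind_truth: tuple[Raster, Raster],
    n_direct: int,
    grid_spacing: float,
    smoothing_radius: float,
    direction_bias: float,
    seed: int,
    anchor_xy: np.ndarray | None = None,
) -> tuple[MetSource, MetSource]:
    """Observe the truth wind field as a direct and a gridded MET source.

    The direct source samples the truth *exactly* at ``n_direct`` station
    cells. When ``anchor_xy`` coordinates are given, the first stations are
    placed there (jittered by one cell) — emulating monitoring stations
    deployed at the contamination sites themselves, as remediation-program
    weather stations are; the remaining stations are placed by jittered
    stratified sampling (one random cell per block of a near-square partition
    of the domain), emulating an airport network sited for spatial coverage. The gridded source emulates an interpolated
    reanalysis product: the truth is spatially smoothed over
    ``smoothing_radius``, a systematic ``direction_bias`` (degrees) is added,
    and the degraded field is sampled on a regular lattice with
    ``grid_spacing`` between points. The degradation is the *only* difference
    between the two arms.
    """
    direction, speed = wind_truth
    grid = direction.grid
    if n_direct < 1:
        raise ValueError("need at least one direct station")
    if grid_spacing <= grid.cell_size:
        raise ValueError("grid_spacing must exceed the cell size")
    extent_x = grid.n_cols * grid.cell_size
    extent_y = grid.n_rows * grid.cell_size
    if grid_spacing > min(extent_x, extent_y):
        raise ValueError("grid_spacing exceeds the grid extent")
    rng = np.random.default_rng(seed)
    xx, yy = grid.cell_centers()

    if anchor_xy is not None and len(anchor_xy) > 0:
        n_anchor = min(len(anchor_xy), n_direct)
        ar, ac = grid.index_of(
            np.asarray(anchor_xy)[:n_anchor, 0], np.asarray(anchor_xy)[:n_anchor, 1]
        )
        jitter = rng.integers(-1, 2, size=(2, n_anchor))
        ar = np.clip(ar + jitter[0], 0, grid.n_rows - 1)
        ac = np.clip(ac + jitter[1], 0, grid.n_cols - 1)
        sr, sc = _stratified_cells(grid.n_rows, grid.n_cols, n_direct - n_anchor, rng)
        rows = np.concatenate([ar, sr]).astype(int)
        cols = np.concatenate([ac, sc]).astype(int)
    else:
        rows, cols = _stratified_cells(grid.n_rows, grid.n_cols, n_direct, rng)
    direct_points = [
        MetPoint(
            id=f"S{i:03d}",
            x=float(xx[r, c]),
            y=float(yy[r, c]),
            direction_deg=float(direction.values[r, c]),
            speed=float(speed.values[r, c]),
            kind="direct",
        )
        for i, (r, c) in enumerate(zip(rows, cols))
    ]

    sigma_cells = smoothing_radius / grid.cell_size
    smooth_dir = (_smooth_direction(direction.values, sigma_cells) + direction_bias) % 360.0
    smooth_spd = (
        gaussian_filter(speed.values, sigma=sigma_cells, mode="reflect")
        if sigma_cells > 0
        else speed.values
    )
    step = int(round(grid_spacing / grid.cell_size))
    offset = step // 2
    gridded_points = []
    i = 0
    for r in range(offset, grid.n_rows, step):
        for c in range(offset, grid.n_cols, step):
            gridded_points.append(
                MetPoint(
                    id=f"G{i:03d}",
                    x=float(xx[r, c]),
                    y=float(yy[r, c]),
                    direction_deg=float(smooth_dir[r, c]),
                    speed=float(max(smooth_spd[r, c], 0.0)),
                    kind="gridded",
                )
            )
            i += 1
    return (
        MetSource(name="direct", points=direct_points, kind="direct"),
        MetSource(name="gridded", points=gridded_points, kind="gridded"),
    )


def generate_ancillary(
    grid: Grid, n_wells: int, n_roads: int, seed: int
) -> tuple[pd.DataFrame, list[LineString], Raster]:
    """Wells with positively skewed hazard indices, road polylines, and NDVI.

    Hazard indices are lognormal (strictly positive, right-skewed). Roads are
    random polylines crossing the domain. NDVI is a smooth field squashed
    into [-1, 1].
    """
    if n_wells < 1 or n_roads < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    wells = pd.DataFrame(
        {
            "x": rng.uniform(xmin, xmax, n_wells),
            "y": rng.uniform(ymin, ymax, n_wells),
            "hazard_index": rng.lognormal(mean=0.0, sigma=0.8, size=n_wells),
        }
    )
    roads = []
    for _ in range(n_roads):
        n_vertices = 5
        xs = np.sort(rng.uniform(xmin, xmax, n_vertices))
        if rng.random() < 0.5:
            xs = xs[::-1]
        ys = rng.uniform(ymin, ymax, n_vertices)
        roads.append(LineString(np.column_stack([xs, ys])))
    ndvi_field = _standardized_grf(grid.shape, sigma_cells=6.0, rng=rng)
    ndvi = Raster(grid, np.tanh(0.6 * ndvi_field + 0.2))
    return wells, roads, ndvi


def generate_validation_samples(
    criteria_stack_truth: list[Raster],
    true_weights: WeightVector | np.ndarray,
    n: int,
    noise_sd: float,
    seed: int,
    intercept: float = 1.0,
    slope: float = 3.0,
) -> list[ValidationSample]:
    """Concentration samples from the known-weight truth exposure surface.

    Locations are uniform over the grid; concentrations follow the log-linear
    link c = exp(intercept + slope * E(x, y) + eps), eps ~ N(0, noise_sd),
    where E is the weighted linear combination of the fuzzified truth criteria
    at the sample's cell. The exponential link makes the marginal distribution
    right-skewed, as stream-sediment uranium concentrations are.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    w = true_weights if isinstance(true_weights, WeightVector) else WeightVector(true_weights)
    if len(w) != len(criteria_stack_truth):
        raise ValueError("one weight per criteria layer required")
    grid = criteria_stack_truth[0].grid
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    exposure = np.zeros(n)
    for wk, layer in zip(w.weights, criteria_stack_truth):
        exposure += wk * layer.sample(xs, ys)
    eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    conc = np.exp(intercept + slope * exposure + eps)
    return [
        ValidationSample(x=float(x), y=float(y), concentration=float(c))
        for x, y, c in zip(xs, ys, conc)
    ]
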