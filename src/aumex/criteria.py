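"""Raw criteria layers for the exposure model.

Eight criteria feed the multi-criteria overlay, mirroring a point-source
exposure susceptibility design around abandoned uranium mines (AUMs):

1. AUM proximity — area-weighted inverse distance to sources within a radius.
2. Downslope drainage — inverse along-path distance from sources to drainage
   zones intersecting each source's downstream flow path.
3. Wind index — a bespoke downwind-susceptibility statistic combining the
   receptor-to-source bearing, the prevailing wind direction, distance, and
   scaled wind speed.
4. Topographic wind exposure — angle between the local terrain surface and
   the plane orthogonal to the wind vector, weighted by scaled speed.
5. Topographic landforms — six TPI/slope classes from valleys to ridges.
6. Road proximity — Euclidean distance to the nearest road segment.
7. Groundwater contamination — IDW interpolation of well hazard indices.
8. NDVI — vegetation index passthrough.

Layers 3 and 4 are the MET-sensitive layers: they change with the wind data
source and drive the source-comparison experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from .met import WindField
from .raster import Grid, Raster, check_aligned

__all__ = [
    "SourcePoint",
    "TerrainDerivatives",
    "Zones",
    "aum_proximity",
    "drainage_layer",
    "idw_hazard",
    "landform_classify",
    "road_proximity",
    "slope_aspect",
    "topographic_exposure",
    "tpi",
    "trace_downstream",
    "voronoi_zones",
    "wind_index",
]

M_PER_KM = 1000.0


@dataclass(frozen=True)
class SourcePoint:
    """An abandoned-mine point source with a surface area (its proximity weight)."""

    id: str
    x: float
    y: float
    area: float  # m^2

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("source area must be positive")


# ---------------------------------------------------------------------------
# terrain derivatives
# ---------------------------------------------------------------------------


@dataclass
class TerrainDerivatives:
    """Slope (degrees), aspect (downslope compass bearing, NaN where flat), TPI."""

    slope: Raster
    aspect: Raster
    tpi: Raster | None = None


def slope_aspect(dem: Raster) -> TerrainDerivatives:
    """Slope and aspect via the Horn 8-neighbour finite-difference stencil.

    Aspect is the compass bearing of steepest descent (0° = north, clockwise)
    and is undefined (NaN) on perfectly flat cells. Edge cells use replicated
    padding.
    """
    z = np.pad(dem.values, 1, mode="edge")
    cell = dem.grid.cell_size
    # Horn 1981 weights; row-1 is north (y decreases with row index)
    gx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * cell)
    gy = (
        (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
        - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
    ) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    flat = (gx == 0) & (gy == 0)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect[flat] = np.nan
    return TerrainDerivatives(
        slope=Raster(dem.grid, slope),
        aspect=Raster(dem.grid, aspect),
    )


def tpi(dem: Raster, radius: float) -> Raster:
    """Topographic position index: elevation minus the circular-neighbourhood mean.

    The centre cell is excluded from its own neighbourhood; neighbourhoods are
    truncated at the grid edge rather than padded.
    """
    cell = dem.grid.cell_size
    if radius < cell:
        raise ValueError("TPI radius must be at least one cell size")
    r = int(radius // cell)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    kernel = ((xx * cell) ** 2 + (yy * cell) ** 2 <= radius**2).astype(float)
    kernel[r, r] = 0.0
    num = ndimage.convolve(dem.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(dem.values), kernel, mode="constant", cval=0.0)
    return dem.with_values(dem.values - num / den)


def landform_classify(tpi_raster: Raster, slope: Raster) -> Raster:
    """Six landform classes from TPI and slope.

    With s the TPI standard deviation: valley (1) TPI <= -s; lower slope (2)
    -s < TPI <= -s/2; flat (3) |TPI| < s/2 and slope <= 5 deg; mid-slope (4)
    |TPI| < s/2 and slope > 5 deg; upper slope (5) s/2 <= TPI < s; ridge (6)
    TPI >= s. Zero-variance TPI degenerates to the flat/mid split by slope.
    """
    check_aligned(tpi_raster, slope, names=["tpi", "slope"])
    t = tpi_raster.values
    s = float(np.std(tpi_raster.valid_values()))
    cls = np.zeros(t.shape, dtype=float)
    if s == 0:
        cls[:] = np.where(slope.values <= 5.0, 3, 4)
        return tpi_raster.with_values(cls)
    cls[t <= -s] = 1
    cls[(t > -s) & (t <= -0.5 * s)] = 2
    mid_band = np.abs(t) < 0.5 * s
    cls[mid_band & (slope.values <= 5.0)] = 3
    cls[mid_band & (slope.values > 5.0)] = 4
    cls[(t >= 0.5 * s) & (t < s)] = 5
    cls[t >= s] = 6
    return tpi_raster.with_values(cls)


# ---------------------------------------------------------------------------
# source-proximity layers
# ---------------------------------------------------------------------------


def aum_proximity(
    grid: Grid, sources: list[SourcePoint], radius: float = 50_000.0
) -> Raster:
    """Sum of area-weighted inverse distances to all sources within ``radius``.

    Distances are floored at half a cell size so that a cell containing a
    source gets a finite value. Cells with no source within the radius are 0.
    """
    if not sources:
        raise ValueError("at least one source required")
    xx, yy = grid.cell_centers()
    floor = grid.cell_size / 2.0
    out = np.zeros(grid.shape)
    for s in sources:
        d = np.hypot(xx - s.x, yy - s.y)
        d = np.maximum(d, floor)
        out += np.where(d <= radius, s.area / d, 0.0)
    return Raster(grid, out)


_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_downstream(dem: Raster, start: SourcePoint) -> list[tuple[int, int]]:
    """D8 steepest-descent flow path from a source to a pit or the grid edge.

    Returns the ordered list of (row, col) cells, starting at the source cell.
    The path follows the neighbour with the steepest elevation drop per unit
    distance and stops at a local minimum (pit) or when leaving the grid; no
    cell repeats.
    """
    if not dem.grid.contains(start.x, start.y):
        raise ValueError(f"source {start.id} lies outside the grid")
    r, c = dem.grid.index_of(start.x, start.y)
    r, c = int(r), int(c)
    if not dem.mask[r, c]:
        raise ValueError(f"source {start.id} starts on a nodata cell")
    z = dem.values
    nrows, ncols = dem.grid.shape
    path = [(r, c)]
    visited = {(r, c)}
    while True:
        best = None
        best_rate = 0.0
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols):
                continue
            dist = np.hypot(dr, dc)
            rate = (z[r, c] - z[rr, cc]) / dist
            if rate > best_rate:
                best_rate = rate
                best = (rr, cc)
        if best is None or best in visited:
            return path
        r, c = best
        path.append(best)
        visited.add(best)


@dataclass
class Zones:
    """A partition of the grid into drainage zones (synthetic HRU stand-ins)."""

    labels: Raster  # integer zone label per cell
    centroids: np.ndarray  # (n_zones, 2) centroid coordinates
    mean_boundary_length: float  # mean zone perimeter, m

    @property
    def n_zones(self) -> int:
        return len(self.centroids)


def voronoi_zones(grid: Grid, n_zones: int, seed: int) -> Zones:
    """Partition the grid into ``n_zones`` Voronoi cells of random seed points."""
    if n_zones < 1:
        raise ValueError("need at least one zone")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    seeds = np.column_stack(
        [rng.uniform(xmin, xmax, n_zones), rng.uniform(ymin, ymax, n_zones)]
    )
    tree = cKDTree(seeds)
    _, labels = tree.query(grid.cell_center_points())
    labels = labels.reshape(grid.shape)
    xx, yy = grid.cell_centers()
    centroids = np.array(
        [
            [xx[labels == k].mean(), yy[labels == k].mean()]
            if np.any(labels == k)
            else seeds[k]
            for k in range(n_zones)
        ]
    )
    # perimeter per zone: lattice edges on the zone boundary (incl. grid border)
    perims = np.zeros(n_zones)
    for axis in (0, 1):
        a = labels
        b = np.roll(labels, -1, axis=axis)
        sl = [slice(None), slice(None)]
        sl[axis] = slice(0, -1)
        diff = a[tuple(sl)] != b[tuple(sl)]
        for k in range(n_zones):
            inner = a[tuple(sl)]
            outer = b[tuple(sl)]
            perims[k] += np.sum(diff & (inner == k)) + np.sum(diff & (outer == k))
    border = 2 * grid.n_rows + 2 * grid.n_cols
    for k in range(n_zones):
        perims[k] += (
            np.sum(labels[0] == k)
            + np.sum(labels[-1] == k)
            + np.sum(labels[:, 0] == k)
            + np.sum(labels[:, -1] == k)
        )
    perims *= grid.cell_size
    return Zones(
        labels=Raster(grid, labels.astype(float)),
        centroids=centroids,
        mean_boundary_length=float(perims.mean()),
    )


def _path_linestring(dem: Raster, path: list[tuple[int, int]]) -> LineString | Point:
    g = dem.grid
    pts = [
        (g.origin_x + (c + 0.5) * g.cell_size, g.origin_y - (r + 0.5) * g.cell_size)
        for r, c in path
    ]
    return Point(pts[0]) if len(pts) == 1 else LineString(pts)


def drainage_layer(
    dem: Raster,
    sources: list[SourcePoint],
    zones: Zones,
    snap_threshold: float | None = None,
) -> Raster:
    """Inverse along-path drainage distance from sources, rasterized by zone.

    For every source a downstream flow path is traced on the DEM. A zone whose
    centroid lies within ``snap_threshold`` of a path is snapped to its nearest
    point on that path, and the along-path distance back to the source is
    accumulated as 1/distance (km^-1). Zones intersecting no path are 0.
    The default threshold is the mean zone boundary length.
    """
    if snap_threshold is None:
        snap_threshold = zones.mean_boundary_length
    if snap_threshold <= 0:
        raise ValueError("snap_threshold must be positive")
    floor_m = dem.grid.cell_size / 2.0
    zone_values = np.zeros(zones.n_zones)
    paths = [_path_linestring(dem, trace_downstream(dem, s)) for s in sources]
    for k, (cx, cy) in enumerate(zones.centroids):
        centroid = Point(cx, cy)
        total = 0.0
        for line in paths:
            if centroid.distance(line) > snap_threshold:
                continue
            d_along = 0.0 if isinstance(line, Point) else line.project(centroid)
            d_km = max(d_along, floor_m) / M_PER_KM
            total += 1.0 / d_km
        zone_values[k] = total
    out = zone_values[zones.labels.values.astype(int)]
    return Raster(dem.grid, out)


# ---------------------------------------------------------------------------
# MET-sensitive layers
# ---------------------------------------------------------------------------


def bearing_deg(from_x, from_y, to_x, to_y):
    """Compass bearing (0 = north, clockwise) from one point toward another."""
    return np.degrees(np.arctan2(to_x - from_x, to_y - from_y)) % 360.0


def wind_index(
    grid: Grid,
    sources: list[SourcePoint],
    wind: WindField,
    speed_scaled: Raster,
    downwind_peak: bool = True,
) -> Raster:
    """Downwind susceptibility index from all sources.

    Per receptor cell i and source j, with theta the bearing from the receptor
    toward the source, beta the cell's prevailing blowing-from direction, D the
    distance in km (floored at half a cell) and Sv the scaled speed, the
    directional factor is

        f = (1 - cos(180 deg + (theta - beta))) / 2  in [0, 1],

    which peaks at 1 for receptors directly downwind (theta = beta) and
    vanishes directly upwind. Terms (f / D) * Sv are summed over sources where
    f > 0.5 (strictly), and the index is the square root of the sum.
    ``downwind_peak=False`` flips the convention by 180 degrees.
    """
    if not sources:
        raise ValueError("at least one source required")
    check_aligned(wind.direction, speed_scaled, names=["wind", "speed_scaled"])
    xx, yy = grid.cell_centers()
    beta = wind.direction.values
    sv = speed_scaled.values
    floor_km = grid.cell_size / 2.0 / M_PER_KM
    phase = 180.0 if downwind_peak else 0.0
    total = np.zeros(grid.shape)
    for s in sources:
        theta = bearing_deg(xx, yy, s.x, s.y)
        f = (1.0 - np.cos(np.radians(phase + theta - beta))) / 2.0
        d_km = np.maximum(np.hypot(xx - s.x, yy - s.y) / M_PER_KM, floor_km)
        # strict cutoff; the 1e-9 guard keeps exact-crosswind cells (f = 0.5
        # up to floating-point rounding of the cosine) excluded
        total += np.where(f > 0.5 + 1e-9, (f / d_km) * sv, 0.0)
    return Raster(grid, np.sqrt(total))


def topographic_exposure(
    terrain: TerrainDerivatives,
    wind: WindField,
    speed_scaled: Raster,
    beta_w: float = 0.0,
) -> Raster:
    """Cosine of the angle between terrain and the plane orthogonal to the wind.

    cos(alpha) = cos(mu) sin(beta_w) + sin(mu) cos(beta_w) cos(delta - gamma),
    weighted by the scaled speed Sv. mu is slope, gamma aspect, delta the
    blowing-from wind direction and beta_w the wind's inclination above the
    horizontal (default 0: horizontal wind, reducing to
    sin(mu) cos(delta - gamma) Sv). Flat cells have undefined aspect; their
    aspect term vanishes with sin(mu) = 0.
    """
    check_aligned(
        terrain.slope, terrain.aspect, wind.direction, speed_scaled,
        names=["slope", "aspect", "wind", "speed_scaled"],
    )
    mu = np.radians(terrain.slope.values)
    bw = np.radians(beta_w)
    delta = np.radians(wind.direction.values)
    gamma = np.radians(np.nan_to_num(terrain.aspect.values))  # flat: sin(mu)=0 anyway
    cos_alpha = np.cos(mu) * np.sin(bw) + np.sin(mu) * np.cos(bw) * np.cos(delta - gamma)
    return Raster(terrain.slope.grid, cos_alpha * speed_scaled.values)


# ---------------------------------------------------------------------------
# ancillary layers
# ---------------------------------------------------------------------------


def road_proximity(grid: Grid, roads: list[LineString]) -> Raster:
    """Per-cell Euclidean distance from the cell centre to the nearest road."""
    if not roads:
        raise ValueError("at least one road required")
    pts = shapely.points(grid.cell_center_points())
    d = np.full(len(pts), np.inf)
    for road in roads:
        d = np.minimum(d, shapely.distance(pts, road))
    return Raster(grid, d.reshape(grid.shape))


def idw_hazard(
    grid: Grid,
    well_xy: np.ndarray,
    well_values: np.ndarray,
    power: float = 2.0,
) -> Raster:
    """Inverse-distance-weighted interpolation of well hazard indices.

    Exact at wells: a cell centre coincident with a well takes its value.
    """
    well_xy = np.asarray(well_xy, dtype=float)
    well_values = np.asarray(well_values, dtype=float)
    if well_xy.ndim != 2 or len(well_xy) == 0:
        raise ValueError("at least one well required")
    centers = grid.cell_center_points()
    d = np.sqrt(((centers[:, None, :] - well_xy[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(centers))
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    out = (w * well_values).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)
    if has_exact.any():
        idx = np.argmax(exact, axis=1)
        out[has_exact] = well_values[idx[has_exact]]
    return Raster(grid, out.reshape(grid.shape))
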