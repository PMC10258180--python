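"""Meteorological data reduction, fusion, and rasterization.

Wind enters the exposure model as a per-cell prevailing direction (degrees,
meteorological "blowing-from" convention) and mean speed. Raw station records
are reduced to a modal wind-rose sector and an arithmetic mean speed; sources
of different kinds (direct station measurements vs. interpolated gridded
reanalysis) are fused under a nearest-neighbour replacement rule; the fused
point set is rasterized onto the analysis grid by nearest-point assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import Grid, Raster

__all__ = [
    "MetPoint",
    "MetSource",
    "WindRecordSeries",
    "WindField",
    "prevailing_direction",
    "combine_sources",
    "rasterize_wind",
    "scale_speed",
    "read_met_csv",
    "write_met_csv",
]


@dataclass(frozen=True)
class MetPoint:
    """A wind summary point: prevailing direction and mean speed at a location.

    ``kind`` distinguishes direct station measurements from points of a
    gridded (interpolated reanalysis) product.
    """

    id: str
    x: float
    y: float
    direction_deg: float
    speed: float
    kind: str = "direct"

    def __post_init__(self) -> None:
        if not 0 <= self.direction_deg < 360:
            object.__setattr__(self, "direction_deg", self.direction_deg % 360.0)
        if self.speed < 0:
            raise ValueError("speed must be nonnegative")
        if self.kind not in ("direct", "gridded"):
            raise ValueError(f"unknown point kind {self.kind!r}")


@dataclass
class MetSource:
    """A labelled collection of wind measurement points."""

    name: str
    points: list[MetPoint]
    kind: str = "direct"  # direct | gridded | mixed

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError(f"MET source {self.name!r} has no points")
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate point ids in source {self.name!r}")

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points])


@dataclass
class WindRecordSeries:
    """Raw (direction, speed) observations for one station."""

    station_id: str
    x: float
    y: float
    directions_deg: np.ndarray
    speeds: np.ndarray

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float) % 360.0
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.directions_deg.size == 0:
            raise ValueError("record series must contain at least one observation")
        if self.directions_deg.shape != self.speeds.shape:
            raise ValueError("direction and speed arrays must have equal length")


@dataclass
class WindField:
    """Per-cell prevailing direction and mean speed on the analysis grid."""

    direction: Raster
    speed: Raster
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.direction.grid != self.speed.grid:
            raise ValueError("direction and speed rasters must share a grid")


def prevailing_direction(series: WindRecordSeries, n_sectors: int = 16) -> MetPoint:
    """Reduce a record series to the modal wind-rose sector and mean speed.

    Directions are binned into ``n_sectors`` equal sectors centred on 0° (the
    conventional wind-rose layout: sector 0 spans [-w/2, w/2) around north).
    The returned direction is the centre of the most populated sector; ties go
    to the lowest sector index. Speed is the arithmetic mean of all speeds.
    """
    if n_sectors < 1 or (360.0 / n_sectors) * n_sectors != 360.0:
        raise ValueError("n_sectors must divide 360 into exactly equal sectors")
    width = 360.0 / n_sectors
    idx = np.floor(series.directions_deg / width + 0.5).astype(int) % n_sectors
    counts = np.bincount(idx, minlength=n_sectors)
    mode_sector = int(np.argmax(counts))  # argmax takes the lowest index on ties
    return MetPoint(
        id=series.station_id,
        x=series.x,
        y=series.y,
        direction_deg=(mode_sector * width) % 360.0,
        speed=float(series.speeds.mean()),
    )


def combine_sources(sources: list[MetSource], k_replace: int = 4) -> MetSource:
    """Fuse MET sources, letting direct stations displace nearby gridded points.

    Direct-only input returns the plain union. When one gridded source is
    present alongside direct sources, the ``k_replace`` gridded points nearest
    to *each* direct station are removed (as a set union, so a gridded point
    shared between stations is removed once), then the surviving gridded
    points are unioned with all direct points.
    """
    if not sources:
        raise ValueError("at least one source required")
    gridded = [s for s in sources if s.kind == "gridded"]
    if len(gridded) > 1:
        raise ValueError("at most one gridded source may be combined")
    direct_points = [p for s in sources if s.kind != "gridded" for p in s.points]
    all_ids = [p.id for s in sources for p in s.points]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate point ids across sources")

    name = "+".join(s.name for s in sources)
    if not gridded:
        return MetSource(name=name, points=list(direct_points), kind="direct")

    grid_points = list(gridded[0].points)
    if not direct_points:
        return MetSource(name=name, points=grid_points, kind="gridded")

    tree = cKDTree(np.array([[p.x, p.y] for p in grid_points]))
    removed: set[int] = set()
    k = min(k_replace, len(grid_points))
    for p in direct_points:
        _, nearest = tree.query([p.x, p.y], k=k)
        removed.update(np.atleast_1d(nearest).tolist())
    survivors = [p for i, p in enumerate(grid_points) if i not in removed]
    return MetSource(name=name, points=direct_points + survivors, kind="mixed")


def rasterize_wind(source: MetSource, grid: Grid) -> WindField:
    """Assign each grid cell the direction/speed of its nearest MET point.

    Planar Euclidean distance from the cell centre; exact distance ties are
    broken toward the lowest point id, and the assignment is invariant to the
    ordering of points within the source.
    """
    points = sorted(source.points, key=lambda p: str(p.id))
    coords = np.array([[p.x, p.y] for p in points])
    centers = grid.cell_center_points()
    # squared distances, argmin returns the first (lowest-id) point on ties
    d2 = ((centers[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dirs = np.array([p.direction_deg for p in points])[nearest].reshape(grid.shape)
    spds = np.array([p.speed for p in points])[nearest].reshape(grid.shape)
    return WindField(
        direction=Raster(grid, dirs),
        speed=Raster(grid, spds),
        source_label=source.name,
    )


def scale_speed(speed: Raster) -> Raster:
    """Divide speeds by the domain maximum, mapping into (0, 1]."""
    vals = speed.valid_values()
    if vals.size == 0 or vals.max() <= 0:
        raise ValueError("cannot scale an all-zero speed raster")
    if vals.min() < 0:
        raise ValueError("speeds must be nonnegative")
    return speed.with_values(speed.values / vals.max())


def write_met_csv(source: MetSource, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in source.points],
            "x": [p.x for p in source.points],
            "y": [p.y for p in source.points],
            "direction_deg": [p.direction_deg for p in source.points],
            "speed": [p.speed for p in source.points],
            "kind": [p.kind for p in source.points],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_met_csv(path: str | Path, name: str | None = None) -> MetSource:
    df = pd.read_csv(path, float_precision="round_trip")
    points = [
        MetPoint(
            id=str(r.id), x=float(r.x), y=float(r.y),
            direction_deg=float(r.direction_deg), speed=float(r.speed), kind=str(r.kind),
        )
        for r in df.itertuples()
    ]
    kinds = {p.kind for p in points}
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    return MetSource(name=name or Path(path).stem, points=points, kind=kind)
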