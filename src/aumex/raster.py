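"""Planar raster container and plain-text (ESRI ASCII grid) I/O.

All layers in the pipeline share a single :class:`Grid`: a row-major cell
lattice with the origin at the *top-left corner* and y decreasing southward.
Coordinates are planar metres (the study design is projected; no geodesy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "Raster", "RasterAlignmentError", "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


class RasterAlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Georeferenced cell lattice shared by every criteria layer.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; at least 8 each.
    cell_size
        Square cell edge length in metres.
    origin_x, origin_y
        Planar coordinates of the *top-left corner* of cell (0, 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid bounding box."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x, y) of cell-center coordinates, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_center_points(self) -> np.ndarray:
        """All cell centers as an (n_cells, 2) array in row-major order."""
        xx, yy = self.cell_centers()
        return np.column_stack([xx.ravel(), yy.ravel()])

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple:
        """Row/col of the cell containing point(s) (x, y), clipped to the grid."""
        col = np.clip(((np.asarray(x) - self.origin_x) // self.cell_size).astype(int), 0, self.n_cols - 1)
        row = np.clip(((self.origin_y - np.asarray(y)) // self.cell_size).astype(int), 0, self.n_rows - 1)
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax


@dataclass
class Raster:
    """A single-band raster: a :class:`Grid` plus a float value matrix."""

    grid: Grid
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise RasterAlignmentError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return ~np.isclose(self.values, self.nodata) & ~np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, values, self.nodata)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at point coordinates."""
        row, col = self.grid.index_of(x, y)
        return self.values[row, col]


def check_aligned(*rasters: Raster, names: list[str] | None = None) -> None:
    """Raise :class:`RasterAlignmentError` naming the first misaligned layer."""
    ref = rasters[0].grid
    for i, r in enumerate(rasters[1:], start=1):
        if r.grid != ref:
            label = names[i] if names else f"layer {i}"
            raise RasterAlignmentError(f"{label} is not aligned with the stack grid")


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write as an ESRI ASCII grid (.asc) — lossless for grid geometry and values."""
    g = raster.grid
    path = Path(path)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with path.open("w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
    )
    values = values.reshape(n_rows, n_cols)
    return Raster(grid, values, nodata=header["nodata_value"])
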