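"""Gridded surfaces: the :class:`RasterGrid` container and text raster I/O.

A grid is a rectangular 2-D array with a simple georeference (origin of the
upper-left corner, square cell size in metres) and explicit nodata semantics.
Grids are serialised as ESRI ASCII rasters (``.asc``), a plain-text format
every GIS reads, so pipelines remain binary-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "MonthlyClimate",
    "read_ascii_grid",
    "write_ascii_grid",
    "minmax_rescale",
]


@dataclass
class RasterGrid:
    """Single-band raster with geotransform and nodata semantics.

    Parameters
    ----------
    values
        2-D array (float for continuous surfaces, int for categorical ones).
    x0, y0
        Projected coordinates (m) of the upper-left corner of the grid.
    cell_size
        Square cell edge length in metres; must be positive.
    nodata
        Sentinel for missing cells. ``NaN`` in float grids is also treated
        as missing.
    crs_label
        Free-text label of the projected CRS; purely informational.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 150.0
    nodata: float = -9999.0
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeference."""
        return replace(self, values=np.asarray(values))

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a projected point."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((self.y0 - y) / self.cell_size))
        return row, col


@dataclass
class MonthlyClimate:
    """Twelve monthly precipitation (mm) and temperature (degC) grids."""

    p: list = field(default_factory=list)
    t: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.p) != 12 or len(self.t) != 12:
            raise ValueError("MonthlyClimate requires 12 P and 12 T grids")
        shape = self.p[0].shape
        for g in [*self.p, *self.t]:
            if g.shape != shape:
                raise ValueError("climate grid shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p[0].shape


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster (text)."""
    path = Path(path)
    rows, cols = grid.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0 - rows * grid.cell_size}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    vals = np.where(grid.valid_mask(), grid.values, grid.nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path, crs_label: str = "local-metric") -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    rows = int(meta["nrows"])
    cell = meta["cellsize"]
    return RasterGrid(
        values=values,
        x0=meta["xllcorner"],
        y0=meta["yllcorner"] + rows * cell,
        cell_size=cell,
        nodata=meta["nodata_value"],
        crs_label=crs_label,
    )


def minmax_rescale(grid: RasterGrid) -> RasterGrid:
    """Rescale a grid linearly onto [0, 1].

    The minimum of the valid cells maps to 0 and the maximum to 1; nodata
    cells are preserved. A constant grid maps to all zeros so that the
    downstream quartile machinery always sees finite values.
    """
    mask = grid.valid_mask()
    if not mask.any():
        raise ValueError("cannot rescale an all-nodata grid")
    v = grid.values.astype(float)
    lo = v[mask].min()
    hi = v[mask].max()
    out = np.full(v.shape, grid.nodata, dtype=float)
    if hi > lo:
        out[mask] = (v[mask] - lo) / (hi - lo)
    else:
        out[mask] = 0.0
    return grid.with_values(out)
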