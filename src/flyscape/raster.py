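"""Planar single-band rasters with plain-text (ESRI ASCII grid) I/O.

All layers in the package -- elevation, ruggedness, topographic position,
ridge masks, distance maps, and flyability predictions -- share this one
container.  Grids are north-up and row-major: row 0 is the northernmost row,
and the cell center of (r, c) is
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``
where ``(origin_x, origin_y)`` is the outer corner of the top-left cell.
Coordinates are planar meters; missing cells are NaN in memory and a sentinel
value on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_min(self) -> float:
        return self.origin_x

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size

    @property
    def centers_x(self) -> np.ndarray:
        """x coordinate of every column's cell centers (length n_cols)."""
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def centers_y(self) -> np.ndarray:
        """y coordinate of every row's cell centers (length n_rows, descending)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        return (
            self.origin_x + (c + 0.5) * self.cell_size,
            self.origin_y - (r + 0.5) * self.cell_size,
        )

    def index_of(self, x, y):
        """Row/column of the cell containing planar point(s) (x, y).

        Points outside the grid yield out-of-range indices; combine with
        :meth:`contains` before indexing ``values``.
        """
        c = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        r = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return r.astype(np.int64), c.astype(np.int64)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y > self.y_min) & (y <= self.y_max)

    def sample(self, x, y):
        """Value of the cell containing each point; NaN outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, np.nan)
        ok = self.contains(x, y)
        if ok.any():
            r, c = self.index_of(x[ok], y[ok])
            r = np.clip(r, 0, self.n_rows - 1)
            c = np.clip(c, 0, self.n_cols - 1)
            out[ok] = self.values[r, c]
        return out if out.size > 1 else float(out[0])

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template raster")
        return RasterGrid(self.origin_x, self.origin_y, self.cell_size, values, self.nodata)

    # -- I/O --------------------------------------------------------------
    def write_asc(self, path) -> None:
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_x!r}\n"
            f"yllcorner {self.y_min!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_asc(cls, path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", NODATA)
        vals = np.where(vals == nodata, np.nan, vals)
        cell = header["cellsize"]
        origin_y = header["yllcorner"] + header["nrows"] * cell
        grid = cls(header["xllcorner"], origin_y, cell, vals, nodata)
        if grid.n_rows != int(header["nrows"]) or grid.n_cols != int(header["ncols"]):
            raise ValueError(f"corrupt ASCII grid {path}: dimensions disagree with header")
        return grid
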