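"""Single-band georeferenced raster grids on a shared planar metric CRS.

All layers in a scene are co-registered *by coordinates*, never by array
index: a 60-m reflectance band and a 1-m canopy height model overlap the
same ground, and values are looked up through ``(x, y)`` coordinates.

Conventions
-----------
* cell ``(row 0, col 0)`` sits at the grid's **top-left** corner,
* a point belongs to the cell whose half-open interval
  ``[x0, x0 + cellsize)`` (and, top-down, ``(y0 - cellsize, y0]``)
  contains it,
* nodata is ``NaN`` in memory and ``-9999`` on disk,
* on-disk format is the ESRI ASCII grid (plain text, ``.asc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


class AlignmentError(ValueError):
    """Two grids that must share a grid definition do not."""


@dataclass
class RasterGrid:
    """A single-band raster: a 2-D float array plus its georeferencing.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values, ``NaN`` for nodata. Stored as float64.
    xmin : float
        x coordinate of the grid's left edge (metres).
    ymax : float
        y coordinate of the grid's top edge (metres).
    cell : float
        Cell size (metres); cells are square.
    """

    data: np.ndarray
    xmin: float = 0.0
    ymax: float = 0.0
    cell: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.xmin - other.xmin) <= tol
            and abs(self.ymax - other.ymax) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def require_same_grid(self, other: "RasterGrid") -> None:
        if not self.same_grid(other):
            raise AlignmentError("grids are not co-registered")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Ground coordinates of the center of cell ``(row, col)``."""
        x = self.xmin + (col + 0.5) * self.cell
        y = self.ymax - (row + 0.5) * self.cell
        return x, y

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell, row-major order.

        Returns flat arrays ``(xs, ys)`` of length ``nrows * ncols``.
        """
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = self.xmin + (cols + 0.5) * self.cell
        ys = self.ymax - (rows + 0.5) * self.cell
        X, Y = np.meshgrid(xs, ys)
        return X.ravel(), Y.ravel()

    def rowcol(self, x, y):
        """Row/column indices of the cells containing points ``(x, y)``.

        Vectorised; points outside the extent get index -1 in both outputs.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.cell).astype(int)
        row = np.floor((self.ymax - y) / self.cell).astype(int)
        # the half-open convention puts y == ymax into row 0
        row = np.where(np.isclose(y, self.ymax), 0, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Values of the cells containing points; ``NaN`` outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.rowcol(x, y)
        out = np.full(x.shape, np.nan)
        ok = row >= 0
        out[ok] = self.data[row[ok], col[ok]]
        return out

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.data.copy(), self.xmin, self.ymax, self.cell)

    def like(self, data: np.ndarray) -> "RasterGrid":
        """A new grid with this grid's georeferencing and the given data."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise AlignmentError("replacement data has a different shape")
        return RasterGrid(data, self.xmin, self.ymax, self.cell)

    # -- I/O ----------------------------------------------------------------

    def write_ascii(self, path) -> None:
        """Write the grid as an ESRI ASCII grid (nodata -9999)."""
        body = np.where(np.isnan(self.data), NODATA, self.data)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xmin!r}\n"
            f"yllcorner {self.ymin!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {NODATA!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", NODATA)
        data = np.where(data == nodata, np.nan, data)
        cell = meta["cellsize"]
        ymax = meta["yllcorner"] + meta["nrows"] * cell
        grid = cls(data, xmin=meta["xllcorner"], ymax=ymax, cell=cell)
        if grid.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError("ASCII grid header does not match data block")
        return grid
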