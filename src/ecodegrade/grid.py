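"""Regular planar grids and plain-text (ESRI ASCII) raster I/O.

A :class:`Grid` stores a 2-D value array over a square-celled grid anchored
at its lower-left corner, row 0 at the top — the layout of the ESRI ASCII
grid format (.asc) used for all raster input and output. Coordinates are
planar meters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, SimulationSpecError

NODATA_DEFAULT = -9999.0


@dataclass
class Grid:
    """Square-celled raster: origin (lower-left corner), cell size, values."""

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # (nrows, ncols), row 0 = northernmost row
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise SimulationSpecError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim != 2 or self.values.size == 0:
            raise SimulationSpecError("grid values must be a non-empty 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        xmin = self.x0 + col * self.cell_size
        ymax = self.y0 + (self.nrows - row) * self.cell_size
        return xmin, ymax - self.cell_size, xmin + self.cell_size, ymax

    def cell_centers(self):
        """(X, Y) center-coordinate arrays of shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; points on the top/right
        edge of the grid fold into the last cell."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.y0) / self.cell_size))
        if col == self.ncols and x <= self.extent[2]:
            col -= 1
        if row_from_bottom == self.nrows and y <= self.extent[3]:
            row_from_bottom -= 1
        return self.nrows - 1 - row_from_bottom, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def aligned_with(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def require_aligned(self, other: "Grid") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"grids are not aligned: origin/cell/shape "
                f"({self.x0},{self.y0},{self.cell_size},{self.values.shape}) vs "
                f"({other.x0},{other.y0},{other.cell_size},{other.values.shape})"
            )

    def with_values(self, values: np.ndarray) -> "Grid":
        return replace(self, values=np.asarray(values))


def make_grid(extent, cell_size: float, fill: float = 0.0) -> Grid:
    """Empty grid covering ``extent = (xmin, ymin, xmax, ymax)``.

    The grid is expanded to a whole number of cells in each direction.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise SimulationSpecError(f"degenerate extent {extent}")
    if cell_size <= 0:
        raise SimulationSpecError(f"cell_size must be > 0, got {cell_size}")
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    if nrows * ncols == 0:
        raise SimulationSpecError("grid would be empty")
    return Grid(xmin, ymin, cell_size, np.full((nrows, ncols), fill, dtype=float))


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a Grid as an ESRI ASCII raster (.asc)."""
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII raster (.asc) into a Grid; NODATA becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    values = np.where(values == nodata, np.nan, values)
    grid = Grid(header["xllcorner"], header["yllcorner"], header["cellsize"],
                values, nodata=nodata)
    if grid.nrows != int(header["nrows"]) or grid.ncols != int(header["ncols"]):
        raise AlignmentError(f"{path}: header shape does not match data")
    return grid
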