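"""Analysis-grid machinery: point-to-cell binning, zonal raster sums,
point densities and the east/west line split.

The analysis grid is a regular, axis-aligned lattice of square cells in
a planar coordinate frame.  Cell membership uses half-open intervals
``[x, x + size) x [y, y + size)`` so every point maps to exactly one
cell and binning is a true partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GridDefinition:
    """A regular grid of square analysis cells.

    Cells are indexed ``(row, col)`` from the lower-left corner;
    ``cell_id = row * n_cols + col`` (row-major, stable).
    """

    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_id(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def cell_index(self, x, y):
        """Map coordinates to (row, col); -1 marks out-of-bounds points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(np.int64)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(ok, row, -1), np.where(ok, col, -1)

    def centroids(self) -> pd.DataFrame:
        """Per-cell centroid coordinates, indexed by cell_id."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return pd.DataFrame({
            "cell_id": np.arange(self.n_cells),
            "x": self.origin[0] + (cols + 0.5) * self.cell_size,
            "y": self.origin[1] + (rows + 0.5) * self.cell_size,
        }).set_index("cell_id")


def bin_points_to_cells(points: pd.DataFrame, grid: GridDefinition,
                        category_col: str = "category"):
    """Count points per cell and per category.

    Parameters
    ----------
    points : DataFrame with columns ``x``, ``y`` and *category_col*.
    grid : GridDefinition

    Returns
    -------
    counts : DataFrame indexed by cell_id (all cells present), one
        column per category appearing in the input.
    n_out_of_bounds : int
        Points falling outside the grid; counted and reported, never
        silently dropped.
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("points carry non-finite coordinates")
    row, col = grid.cell_index(x, y)
    inb = row >= 0
    cid = grid.cell_id(row[inb], col[inb])
    cats = pd.Categorical(points[category_col].to_numpy()[inb])
    counts = np.zeros((grid.n_cells, len(cats.categories)), dtype=np.int64)
    np.add.at(counts, (cid, cats.codes), 1)
    out = pd.DataFrame(counts, columns=list(cats.categories))
    out.index.name = "cell_id"
    return out, int((~inb).sum())


@dataclass(frozen=True)
class Raster:
    """An axis-aligned gridded field with its own (finer) resolution.

    ``values`` is row 0 = southernmost row, matching the analysis grid's
    lower-left indexing.  Only square, axis-aligned pixels are supported.
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.asarray(self.values).ndim != 2:
            raise ValueError("raster values must be 2-D (axis-aligned)")


def zonal_sum(raster: Raster, grid: GridDefinition) -> pd.Series:
    """Sum raster values per analysis cell under the pixel-center rule.

    Each pixel contributes to exactly one cell (the one containing its
    center); pixels whose center falls outside the grid are dropped, so
    the global sum is conserved for in-bounds pixels.
    """
    vals = np.asarray(raster.values, dtype=float)
    nr, nc = vals.shape
    px = raster.origin[0] + (np.arange(nc) + 0.5) * raster.pixel_size
    py = raster.origin[1] + (np.arange(nr) + 0.5) * raster.pixel_size
    X, Y = np.meshgrid(px, py)
    row, col = grid.cell_index(X.ravel(), Y.ravel())
    inb = row >= 0
    cid = grid.cell_id(row[inb], col[inb])
    sums = np.bincount(cid, weights=vals.ravel()[inb], minlength=grid.n_cells)
    return pd.Series(sums, index=pd.RangeIndex(grid.n_cells, name="cell_id"))


def point_density(points: pd.DataFrame, grid: GridDefinition) -> pd.Series:
    """Points per unit cell area, per cell (count / cell_area)."""
    pts = points.assign(category="_all")
    counts, _ = bin_points_to_cells(pts, grid)
    if "_all" not in counts.columns:  # no points at all
        return pd.Series(0.0, index=counts.index)
    return counts["_all"] / grid.cell_area


@dataclass(frozen=True)
class LineSplit:
    """A straight line through ``a`` and ``b`` splitting the plane.

    The "east" side is the right-hand side of the line oriented a -> b
    (2-D cross product ``(b - a) x (p - a)`` negative); points exactly
    on the line count as east.  The default endpoints trace the
    Heihe-Tengchong line south-to-north (Tengchong first) so that, in
    lon/lat coordinates, the densely populated side of China is east.
    """

    a: tuple[float, float] = (98.497, 25.020)   # Tengchong
    b: tuple[float, float] = (127.528, 50.245)  # Heihe

    def __post_init__(self):
        if tuple(self.a) == tuple(self.b):
            raise ValueError("degenerate line: endpoints coincide")


def side_of_line(points, line: LineSplit):
    """Classify point(s) as ``"east"`` or ``"west"`` of the split line.

    ``points`` is an ``(n, 2)`` array-like or a single ``(x, y)`` pair.
    Cross product sign rule: east iff ``(b-a) x (p-a) <= 0`` (on-line
    points deterministically east).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(p).all():
        raise ValueError("non-finite point coordinates")
    ax, ay = line.a
    bx, by = line.b
    cross = (bx - ax) * (p[:, 1] - ay) - (by - ay) * (p[:, 0] - ax)
    sides = np.where(cross <= 0, "east", "west")
    if np.asarray(points).ndim == 1:
        return str(sides[0])
    return sides


def broadcast_city_values(city_of_cell: pd.Series,
                          city_values: pd.Series) -> pd.Series:
    """Assign a city-level value (e.g. cumulative case count) to every
    member cell of that city."""
    missing = set(city_of_cell.unique()) - set(city_values.index)
    if missing:
        raise KeyError(f"no value for cities: {sorted(missing)!r}")
    out = city_of_cell.map(city_values)
    out.name = city_values.name
    return out


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI-ASCII-style grid)

def read_ascii_raster(path) -> Raster:
    """Read an ESRI-ASCII-style grid (ncols/nrows/xll/yll/cellsize header).

    The file stores rows north-to-south; they are flipped so that
    ``values[0]`` is the southernmost row, matching :class:`Raster`.
    """
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        body = np.loadtxt(fh, dtype=float)
    vals = np.atleast_2d(body)[::-1]  # south-up
    if "nodata_value" in header:
        vals = np.where(vals == header["nodata_value"], np.nan, vals)
    return Raster(
        values=vals,
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        pixel_size=header.get("cellsize", 1.0),
    )


def write_ascii_raster(raster: Raster, path) -> None:
    vals = np.asarray(raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {vals.shape[1]}\n")
        fh.write(f"nrows {vals.shape[0]}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.pixel_size}\n")
        np.savetxt(fh, vals[::-1], fmt="%.10g")
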