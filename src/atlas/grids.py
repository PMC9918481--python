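"""Gridded covariate rasters: container, block aggregation, point extraction.

In memory a grid holds float64 values with NaN marking missing cells; the
north-up affine geotransform is the usual raster convention (row 0 is the
northern edge). On disk grids are float32 GeoTIFFs with nodata −9999 (see
:mod:`atlas.geoio`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform with square cells.

    ``x0`` is the west edge, ``y1`` the north edge, ``cell`` the cell size
    in km. Cell ``(row, col)`` spans ``[x0 + col*cell, x0 + (col+1)*cell)``
    in x and ``(y1 - (row+1)*cell, y1 - row*cell]`` in y (half-open cell
    ownership: a point on a vertical cell edge belongs to the cell on its
    right; a point on a horizontal edge belongs to the cell below it in row
    order, i.e. the cell whose *top* edge it lies on).
    """

    x0: float
    y1: float
    cell: float

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return x and y coordinates of cell centers as 1-D arrays (cols, rows)."""
        ny, nx = shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y1 - (np.arange(ny) + 0.5) * self.cell
        return xs, ys

    def index(self, x: np.ndarray, y: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open ownership rule.

        Points exactly on the outer east/south boundary are assigned to the
        last column/row so that the closed extent is fully covered.
        """
        ny, nx = shape
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y1 - np.asarray(y, float)) / self.cell).astype(int)
        # y exactly on a cell's top edge: (y1 - y)/cell is an integer k and the
        # point belongs to row k; floor already does this. Outer boundaries:
        col = np.where((col == nx) & np.isclose(x, self.x0 + nx * self.cell), nx - 1, col)
        row = np.where((row == ny) & np.isclose(y, self.y1 - ny * self.cell), ny - 1, row)
        # points exactly on the north edge land at row = 0 via floor(0) = 0,
        # but floating subtraction can give -0.0 -> row 0 anyway.
        row = np.where((row == -1) & np.isclose(y, self.y1), 0, row)
        return row, col


@dataclass
class CovariateGrid:
    """A single gridded covariate (or prediction) surface.

    ``values`` is a 2-D float64 array, NaN = missing; ``transform`` places
    it in planar-km space; ``name`` identifies the layer.
    """

    values: np.ndarray
    transform: GridTransform
    name: str = "layer"
    nodata: float = NODATA

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {v.shape}")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return np.isnan(self.values)

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "CovariateGrid":
        return CovariateGrid(values=values, transform=self.transform,
                             name=self.name if name is None else name, nodata=self.nodata)


def aggregate_grid(grid: CovariateGrid, factor: int) -> CovariateGrid:
    """Aggregate a grid by block means over ``factor × factor`` windows.

    Missing (NaN) cells are ignored within each block; an all-missing block
    yields a missing output cell. Partial blocks at the east/south edges are
    averaged over the cells they do contain. The geotransform cell size is
    scaled by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return grid.copy_with(grid.values.copy())
    v = grid.values
    ny, nx = v.shape
    valid = (~np.isnan(v)).astype(float)
    filled = np.where(np.isnan(v), 0.0, v)
    row_idx = np.arange(0, ny, factor)
    col_idx = np.arange(0, nx, factor)
    sums = np.add.reduceat(np.add.reduceat(filled, row_idx, axis=0), col_idx, axis=1)
    counts = np.add.reduceat(np.add.reduceat(valid, row_idx, axis=0), col_idx, axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    t = grid.transform
    return CovariateGrid(values=out, transform=GridTransform(t.x0, t.y1, t.cell * factor),
                         name=grid.name, nodata=grid.nodata)


def extract_at_points(grids: list[CovariateGrid], points: np.ndarray) -> np.ndarray:
    """Extract grid values at point locations (nearest-cell / containing-cell rule).

    Parameters
    ----------
    grids
        Grids sharing one geotransform and shape.
    points
        ``(n, 2)`` array of (x, y) in km.

    Returns
    -------
    ``(n, k)`` design-matrix block of covariate values; NaN where a point
    falls on a missing cell.

    Raises
    ------
    ValueError
        If any point lies outside the grid bounds (offending points listed),
        or the grids disagree in shape/transform.
    """
    if not grids:
        raise ValueError("no grids supplied")
    t0, s0 = grids[0].transform, grids[0].shape
    for g in grids[1:]:
        if g.shape != s0 or g.transform != t0:
            raise ValueError(f"grid {g.name!r} shape/transform mismatch with {grids[0].name!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    ny, nx = s0
    xmax = t0.x0 + nx * t0.cell
    ymin = t0.y1 - ny * t0.cell
    bad = (x < t0.x0) | (x > xmax) | (y < ymin) | (y > t0.y1)
    if bad.any():
        offenders = pts[bad][:10].tolist()
        raise ValueError(f"{int(bad.sum())} point(s) outside grid bounds, e.g. {offenders}")
    row, col = t0.index(x, y, s0)
    return np.column_stack([g.values[row, col] for g in grids])
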