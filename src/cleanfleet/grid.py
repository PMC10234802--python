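"""Regular square-cell analysis grid in abstract planar meter coordinates.

The analysis unit throughout the package is a square grid cell (the study
design uses roughly 300 m x 300 m cells). Coordinates are plain Euclidean
meters with the grid origin at (0, 0); no CRS or geodesy is involved, since
every downstream quantity only needs planar lengths and containment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import box

from .errors import ConfigError

__all__ = ["GridCell", "Grid", "generate_grid"]


@dataclass(frozen=True)
class GridCell:
    """One square cell of the analysis grid.

    ``id`` is the row-major integer index (opaque to consumers; use
    :meth:`Grid.cell_id` to construct it). ``row`` counts from the south
    edge, ``col`` from the west edge, both 0-based.
    """

    id: int
    row: int
    col: int
    polygon: object = field(repr=False, compare=False)  # shapely Polygon


@dataclass(frozen=True)
class Grid:
    """A ``nrows`` x ``ncols`` lattice of square cells of side ``cell_size``."""

    nrows: int
    ncols: int
    cell_size: float
    cells: tuple = field(repr=False, compare=False)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def width(self) -> float:
        return self.ncols * self.cell_size

    @property
    def height(self) -> float:
        return self.nrows * self.cell_size

    @property
    def bounds(self):
        """(xmin, ymin, xmax, ymax) of the grid envelope."""
        return (0.0, 0.0, self.width, self.height)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"cell ({row}, {col}) outside {self.nrows}x{self.ncols} grid")
        return row * self.ncols + col

    def rowcol(self, cell_id: int):
        if not (0 <= cell_id < self.n_cells):
            raise IndexError(f"cell id {cell_id} outside grid of {self.n_cells} cells")
        return divmod(cell_id, self.ncols)

    def cell(self, row: int, col: int) -> GridCell:
        return self.cells[self.cell_id(row, col)]

    def cell_center(self, row: int, col: int):
        s = self.cell_size
        return ((col + 0.5) * s, (row + 0.5) * s)

    def contains_point(self, x: float, y: float) -> bool:
        """Point-in-envelope test; the outer boundary counts as inside."""
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height


def generate_grid(nrows: int, ncols: int, cell_size: float) -> Grid:
    """Build a rectangular grid of square cells.

    Parameters
    ----------
    nrows, ncols : int
        Lattice dimensions; both must be at least 2 (a single row or column
        cannot carry a meaningful contiguity structure).
    cell_size : float
        Side length of every cell, in meters; must be positive.
    """
    if not (isinstance(nrows, (int,)) and isinstance(ncols, (int,))):
        raise ConfigError("nrows and ncols must be integers")
    if nrows < 2 or ncols < 2:
        raise ConfigError(f"grid must be at least 2x2, got {nrows}x{ncols}")
    if not cell_size > 0:
        raise ConfigError(f"cell_size must be positive, got {cell_size}")
    s = float(cell_size)
    cells = []
    for row in range(nrows):
        y0 = row * s
        for col in range(ncols):
            x0 = col * s
            cells.append(
                GridCell(
                    id=row * ncols + col,
                    row=row,
                    col=col,
                    polygon=box(x0, y0, x0 + s, y0 + s),
                )
            )
    return Grid(nrows=nrows, ncols=ncols, cell_size=s, cells=tuple(cells))
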