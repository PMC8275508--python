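"""Shared grid geometry for co-registered raster layers.

All gridded objects in the package (predictor stacks, probability maps,
band maps, population rasters) carry the same :class:`GridGeometry` so that
cellwise overlays are well defined.  Row 0 is the southernmost row; the cell
with indices (row, col) covers the half-open square
``[x_origin + col*cell_size, x_origin + (col+1)*cell_size) ×
[y_origin + row*cell_size, y_origin + (row+1)*cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised when grids that must be co-registered are not."""


@dataclass(frozen=True)
class GridGeometry:
    """Origin (lower-left corner), square cell size and grid shape.

    ``cell_size`` is in kilometres; cell area is ``cell_size**2`` km².
    """

    x_origin: float
    y_origin: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        """Cell area in km²."""
        return self.cell_size ** 2

    @property
    def x_max(self) -> float:
        return self.x_origin + self.ncols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.nrows * self.cell_size

    def contains(self, x, y):
        """Vectorised point-in-extent test (half-open upper edges)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_origin)
            & (x < self.x_max)
            & (y >= self.y_origin)
            & (y < self.y_max)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map continuous coordinates to (row, col) indices.

        Uses half-open cell intervals, so a point exactly on a lower cell
        edge belongs to that cell.  Points outside the extent raise.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not np.all(self.contains(x, y)):
            raise GeometryError("coordinates outside grid extent")
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((y - self.y_origin) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (row + 0.5) * self.cell_size
        return x, y


def require_same_geometry(*geoms: GridGeometry) -> GridGeometry:
    """Assert all geometries are identical; return the common one."""
    first = geoms[0]
    for g in geoms[1:]:
        if g != first:
            raise GeometryError(f"geometry mismatch: {g} != {first}")
    return first
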