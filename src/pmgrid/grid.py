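"""Regular planar study grid with row-major integer cell identifiers.

The study domain is an abstract planar grid in kilometres (no map
projection): coordinates act purely as spatial covariates and distance
inputs, so easting/northing in km carry all the information the model
needs. Cells are unit squares of ``cell_size`` km, identified by a
row-major integer ``cell_id = row * nx + col``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the study grid.

    Parameters
    ----------
    x0, y0
        Easting/northing of the grid's lower-left corner, km.
    cell_size
        Cell edge length, km (1 km in the reference configuration).
    nx, ny
        Number of columns and rows.
    """

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"grid must be at least 1x1, got nx={self.nx} ny={self.ny}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def rowcol_to_cell(self, row, col):
        return np.asarray(row) * self.nx + np.asarray(col)

    def cell_to_rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.nx, cell_id % self.nx

    def centroid(self, cell_id):
        """Easting/northing (km) of cell centroids."""
        row, col = self.cell_to_rowcol(cell_id)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return x, y

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroids of every cell, in cell-id order."""
        return self.centroid(self.cell_ids)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.nx * self.cell_size)
            & (y >= self.y0)
            & (y < self.y0 + self.ny * self.cell_size)
        )

    def point_to_cell(self, x, y):
        """Cell containing each point, half-open convention [left, right) x [bottom, top).

        Raises
        ------
        ValueError
            If any point falls outside the grid; the offending point is named.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()[0]
            bx = np.atleast_1d(x)[bad]
            by = np.atleast_1d(y)[bad]
            raise ValueError(f"point ({bx}, {by}) lies outside the grid")
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        return self.rowcol_to_cell(row, col)
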