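"""Raster grid geometry shared by every gridded layer.

All rasters in a run live on one grid: row-major arrays, row 0 at the
northern edge, cell-centre registration. World coordinates are metres in
an arbitrary projected system (the synthetic generator uses a local
origin at the grid's south-west corner).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: cell size (m), south-west corner, shape."""

    cell_size: float
    x0: float
    y0: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """World (x, y) of a cell centre; row 0 is the northern row."""
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (self.rows - row - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) containing a world point; raises if outside."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = self.rows - 1 - int(np.floor((y - self.y0) / self.cell_size))
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid extent")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x0 <= x <= self.x0 + self.cols * self.cell_size
            and self.y0 <= y <= self.y0 + self.rows * self.cell_size
        )
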