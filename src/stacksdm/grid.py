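"""Planar raster grid and multi-layer climate stack containers.

The pipeline works on a flat, equal-area grid of square cells indexed
(row, col), with row 0 at the grid origin (south-west corner) and
coordinates measured in kilometres. Every cell therefore covers exactly
``cell_size_km ** 2`` square kilometres, which keeps all downstream area
accounting exact (100 km^2 per cell at the 10 km default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; must be >= 1.
    cell_size_km
        Side of a square cell in km (default 10, i.e. 100 km^2 cells).
    origin
        (x_km, y_km) of the grid's lower-left corner.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 10.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        x0, y0 = self.origin
        return (x0, y0,
                x0 + self.n_cols * self.cell_size_km,
                y0 + self.n_rows * self.cell_size_km)

    def cell_of(self, x_km: float, y_km: float) -> Tuple[int, int]:
        """Map a point to its containing cell.

        Cell membership uses half-open intervals [edge, edge + cell_size):
        a point exactly on a shared edge belongs to the cell on the
        upper/right side. Points outside the extent raise ``ValueError``.
        """
        x0, y0 = self.origin
        col = int(np.floor((x_km - x0) / self.cell_size_km))
        row = int(np.floor((y_km - y0) / self.cell_size_km))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x_km}, {y_km}) outside grid extent {self.extent}")
        return row, col

    def cell_center(self, row: int, col: int) -> Tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size_km,
                y0 + (row + 0.5) * self.cell_size_km)


@dataclass
class ClimateStack:
    """Named raster layers on a shared grid for one climate scenario."""

    grid: GridSpec
    scenario_id: str
    layers: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self._check_layer(name, arr)

    def _check_layer(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"layer {name!r} contains non-finite values")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"unknown layer {name!r}; have {self.layer_names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def add_layer(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        self._check_layer(name, arr)
        self.layers[name] = arr

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Flattened (n_cells, n_layers) design matrix, C cell order."""
        names = names if names is not None else self.layer_names
        return np.column_stack([self[n].ravel() for n in names])

    def copy(self, scenario_id: str | None = None) -> "ClimateStack":
        return ClimateStack(
            grid=self.grid,
            scenario_id=scenario_id or self.scenario_id,
            layers={k: v.copy() for k, v in self.layers.items()},
        )
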