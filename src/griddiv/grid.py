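"""Rectangular analysis grid and per-cell scalar layers.

Cells are indexed 0-based and row-major: cell id ``r * n_cols + c``.
Row 0 is the northernmost row (the origin is the centroid of the
top-left cell), matching the convention of latitude/longitude rasters
read top-down. Geographic metadata lives only here; every other module
works with flat cell ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DiversityLayer", "shift_mask", "QUEEN_OFFSETS"]

#: The eight king-move offsets (drow, dcol) of a queen/8-neighbourhood.
QUEEN_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

ROOK_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions; both must be at least 2.
    cell_size:
        Cell edge length in degrees (nominally 0.5).
    origin:
        ``(lon, lat)`` of the centroid of the top-left cell.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"({row}, {col}) outside {self.n_rows} x {self.n_cols} grid")
        return row * self.n_cols + col

    def rowcol(self, cell: int) -> tuple[int, int]:
        if not 0 <= cell < self.n_cells:
            raise IndexError(f"cell {cell} outside grid")
        return divmod(cell, self.n_cols)

    def centroid(self, cell: int) -> tuple[float, float]:
        """Lon/lat centroid of a cell."""
        row, col = self.rowcol(cell)
        lon0, lat0 = self.origin
        return (lon0 + col * self.cell_size, lat0 - row * self.cell_size)

    def cell_bounds(self, cell: int) -> tuple[float, float, float, float]:
        """``(min_lon, min_lat, max_lon, max_lat)`` of a cell."""
        lon, lat = self.centroid(cell)
        h = self.cell_size / 2.0
        return (lon - h, lat - h, lon + h, lat + h)

    def to_array(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat per-cell vector to (n_rows, n_cols)."""
        flat = np.asarray(flat)
        return flat.reshape(self.n_rows, self.n_cols)

    def neighbors(self, cell: int, scheme: str = "queen") -> np.ndarray:
        """Cell ids adjacent to ``cell`` under rook (4) or queen (8) adjacency."""
        offsets = QUEEN_OFFSETS if scheme == "queen" else ROOK_OFFSETS
        row, col = self.rowcol(cell)
        out = []
        for dr, dc in offsets:
            r, c = row + dr, col + dc
            if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                out.append(r * self.n_cols + c)
        return np.array(sorted(out), dtype=int)


def shift_mask(mask: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Shift a 2-D boolean mask by one grid step without wraparound.

    Cells shifted off the edge are dropped; vacated cells are False.
    """
    out = np.zeros_like(mask)
    nr, nc = mask.shape
    rs_src = slice(max(0, -drow), min(nr, nr - drow))
    cs_src = slice(max(0, -dcol), min(nc, nc - dcol))
    rs_dst = slice(max(0, drow), min(nr, nr + drow))
    cs_dst = slice(max(0, dcol), min(nc, nc + dcol))
    out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


@dataclass
class DiversityLayer:
    """A per-cell scalar surface (TD, SES-MPD/NRI, FDis, stability ...).

    ``values`` is a flat float vector of length ``grid.n_cells``; NaN
    marks cells where the metric is undefined (outside the analysis
    mask, or below the richness needed to compute it).
    """

    grid: GridSpec
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError(
                f"layer has {self.values.size} values for a "
                f"{self.grid.n_cells}-cell grid"
            )

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def as_array(self) -> np.ndarray:
        return self.grid.to_array(self.values)
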