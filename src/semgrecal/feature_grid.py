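"""Center-out rearrangement of PC scores into the 5x5 grid fed to the CNN.

Each channel's 25 PC scores are laid out on a 5x5 matrix so that the most
significant component sits at the center and the least significant ones at
the corners. Because a valid 4x4 convolution over a 5x5 grid covers the
center cell in every filter position, the dominant components contribute to
every feature map. The layout is a pure permutation: it conserves the score
multiset and is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["GridLayout", "FeatureGrid", "center_out_order", "rearrange_scores",
           "unrearrange_scores"]


@dataclass
class GridLayout:
    """Bijection from PC rank (1-based) to grid cell.

    ``rank_to_cell[r - 1]`` is the ``(row, col)`` of rank ``r``.
    """

    grid_size: int
    rank_to_cell: np.ndarray

    def cell_of_rank(self, rank: int) -> tuple[int, int]:
        row, col = self.rank_to_cell[rank - 1]
        return int(row), int(col)

    def as_permutation(self) -> np.ndarray:
        """Flat-index permutation: entry r-1 is row*grid_size + col of rank r."""
        return self.rank_to_cell[:, 0] * self.grid_size + self.rank_to_cell[:, 1]


@dataclass
class FeatureGrid:
    """Rearranged scores: ``values`` is grid_size x grid_size x n_channels."""

    values: np.ndarray


def center_out_order(grid_size: int = 5) -> GridLayout:
    """Deterministic center-out layout.

    Cells are sorted by Euclidean distance from the center, ascending; ties
    are broken clockwise starting from the cell directly above the center.
    Rank 1 thus lands at the center and the four lowest ranks at the corners.
    """
    if grid_size % 2 == 0 or grid_size < 1:
        raise ParameterError(f"grid_size must be odd and positive, got {grid_size}")
    c = grid_size // 2
    cells = []
    for row in range(grid_size):
        for col in range(grid_size):
            dr, dc = row - c, col - c
            dist = np.hypot(dr, dc)
            # clockwise angle from "straight up": up -> 0, right -> pi/2, ...
            angle = np.arctan2(dc, -dr) % (2 * np.pi) if (dr, dc) != (0, 0) else 0.0
            cells.append((dist, angle, row, col))
    cells.sort()
    rank_to_cell = np.array([(row, col) for _, _, row, col in cells], dtype=np.int64)
    return GridLayout(grid_size=grid_size, rank_to_cell=rank_to_cell)


def rearrange_scores(scores: np.ndarray, layout: GridLayout) -> FeatureGrid:
    """Place score row ``r`` (rank r+1) at ``layout``'s cell for that rank.

    ``scores`` is (grid_size**2) x n_channels; the result is
    grid_size x grid_size x n_channels.
    """
    scores = np.asarray(scores)
    g = layout.grid_size
    if scores.shape[0] != g * g:
        raise ParameterError(
            f"expected {g * g} score rows for a {g}x{g} grid, got {scores.shape[0]}")
    values = np.empty((g, g) + scores.shape[1:], dtype=scores.dtype)
    rows, cols = layout.rank_to_cell[:, 0], layout.rank_to_cell[:, 1]
    values[rows, cols] = scores
    return FeatureGrid(values=values)


def unrearrange_scores(grid: FeatureGrid | np.ndarray, layout: GridLayout) -> np.ndarray:
    """Exact inverse of :func:`rearrange_scores`."""
    values = grid.values if isinstance(grid, FeatureGrid) else np.asarray(grid)
    rows, cols = layout.rank_to_cell[:, 0], layout.rank_to_cell[:, 1]
    return values[rows, cols]


def rearrange_batch(scores: np.ndarray, layout: GridLayout) -> np.ndarray:
    """Vectorized rearrangement of N x K x C scores to N x g x g x C grids."""
    scores = np.asarray(scores)
    g = layout.grid_size
    if scores.shape[1] != g * g:
        raise ParameterError(
            f"expected {g * g} scores per segment, got {scores.shape[1]}")
    out = np.empty((scores.shape[0], g, g) + scores.shape[2:], dtype=scores.dtype)
    rows, cols = layout.rank_to_cell[:, 0], layout.rank_to_cell[:, 1]
    out[:, rows, cols] = scores
    return out
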