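"""Toroidal lattice topology with restricted square connectivity domains.

Each neural cell sits on an H x W rectangular grid wrapped on a torus
(cyclic boundary conditions on both axes).  A cell is coupled to every
other cell inside the m x m square centred on it ("InBar"-style vicinity),
giving each cell exactly M = m**2 - 1 presynaptic neighbors regardless of
position.  Cell indices are row-major and 0-based; coordinates wrap by
Euclidean modulo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when grid or experiment parameters violate their contracts."""


@dataclass(frozen=True)
class TorusGrid:
    """An H x W toroidal lattice with m x m connectivity domains.

    Attributes
    ----------
    H, W : int
        Lattice height (rows) and width (columns).
    m : int
        Edge of the square connectivity domain; odd, ``3 <= m <= min(H, W)``.
    """

    H: int
    W: int
    m: int
    _nbr: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.H < 1 or self.W < 1:
            raise ConfigurationError(f"grid dimensions must be positive, got {self.H}x{self.W}")
        if self.m % 2 == 0:
            raise ConfigurationError(f"connectivity edge m must be odd, got m={self.m}")
        if self.m < 3:
            raise ConfigurationError(f"connectivity edge m must be >= 3, got m={self.m}")
        if self.m > min(self.H, self.W):
            raise ConfigurationError(
                f"connectivity edge m={self.m} exceeds min(H, W)={min(self.H, self.W)}"
            )
        object.__setattr__(self, "_nbr", _neighbor_table(self.H, self.W, self.m))

    @property
    def N(self) -> int:
        """Total number of cells (binary pixels per frame)."""
        return self.H * self.W

    @property
    def M(self) -> int:
        """Connectivity: neighbors per cell, m**2 - 1."""
        return self.m * self.m - 1

    @property
    def neighbor_table(self) -> np.ndarray:
        """(N, M) int32 array; row i lists neighbors of cell i in scan order."""
        return self._nbr

    def cell_index(self, row: int, col: int) -> int:
        return (row % self.H) * self.W + (col % self.W)

    def cell_coords(self, i: int) -> tuple[int, int]:
        return divmod(int(i), self.W)


def build_grid(H: int, W: int, m: int) -> TorusGrid:
    """Validate parameters and construct a :class:`TorusGrid`.

    Examples
    --------
    >>> g = build_grid(5, 5, 3)
    >>> g.N, g.M
    (25, 8)
    """
    return TorusGrid(int(H), int(W), int(m))


def _neighbor_table(H: int, W: int, m: int) -> np.ndarray:
    """Precompute the (N, M) neighbor index table.

    Neighbor ordering is a fixed row-major scan of offsets
    (-h..h) x (-h..h), h = (m-1)//2, skipping (0, 0).  Weight vectors are
    aligned with this ordering everywhere in the package.
    """
    h = (m - 1) // 2
    offsets = [(dr, dc) for dr in range(-h, h + 1) for dc in range(-h, h + 1) if (dr, dc) != (0, 0)]
    rows = np.arange(H)[:, None]  # (H, 1)
    cols = np.arange(W)[None, :]  # (1, W)
    nbr = np.empty((H * W, len(offsets)), dtype=np.int32)
    for k, (dr, dc) in enumerate(offsets):
        r = (rows + dr) % H
        c = (cols + dc) % W
        nbr[:, k] = (r * W + c).ravel()
    nbr.setflags(write=False)
    return nbr


def neighbors(grid: TorusGrid, i: int) -> np.ndarray:
    """Ordered neighbor indices of cell ``i`` (length M, row-major offset scan)."""
    if not 0 <= i < grid.N:
        raise IndexError(f"cell index {i} out of range for N={grid.N}")
    return grid.neighbor_table[i]
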