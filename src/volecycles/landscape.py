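"""Binary-habitat landscapes: optimal vole habitat patches in a hostile matrix.

A landscape is a rectangular grid of square cells.  A fixed fraction of the
total area is optimal vole habitat, divided into ``n_patches`` congruent
square patches centred on a regular sqrt(n) x sqrt(n) lattice; everything
else is matrix habitat, which voles can traverse but in which they cannot
feed or breed.  Fragmentation is varied by splitting the same total habitat
area into more, smaller patches.

Coordinates are 0-based integer cell indices, origin at the bottom-left
corner, half-open bounds ``0 <= x < width_cells``.  Edges are reflecting:
agents cannot leave the grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

OPTIMAL = 1
MATRIX = 0


@dataclass
class Landscape:
    """A binary-habitat grid with equally sized, regularly spaced patches.

    Attributes
    ----------
    width_m, height_m : int
        Physical dimensions in metres.
    cell_size_m : int
        Side of one grid cell in metres (1 m in the full-scale system;
        larger values give scaled-down desk runs).
    habitat : ndarray of uint8, shape (width_cells, height_cells)
        ``OPTIMAL`` (1) or ``MATRIX`` (0) per cell.
    patch_ids : ndarray of int32
        Patch index for OPTIMAL cells, -1 for matrix.
    n_patches : int
        Number of habitat patches (a perfect square).
    habitat_fraction : float
        Target fraction of the total area that is optimal habitat.
    """

    width_m: int
    height_m: int
    habitat_fraction: float
    n_patches: int
    cell_size_m: int = 1
    habitat: np.ndarray = field(repr=False, default=None)
    patch_ids: np.ndarray = field(repr=False, default=None)

    @property
    def width_cells(self) -> int:
        return self.width_m // self.cell_size_m

    @property
    def height_cells(self) -> int:
        return self.height_m // self.cell_size_m

    @property
    def n_habitat_cells(self) -> int:
        return int(self.habitat.sum())

    @property
    def habitat_area_m2(self) -> float:
        return self.n_habitat_cells * self.cell_size_m**2

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.width_cells and 0 <= y < self.height_cells

    def to_json(self) -> str:
        """Header describing the landscape; the raster is reproducible from it."""
        return json.dumps(
            {
                "width_m": self.width_m,
                "height_m": self.height_m,
                "habitat_fraction": self.habitat_fraction,
                "n_patches": self.n_patches,
                "cell_size_m": self.cell_size_m,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "Landscape":
        return build_landscape(**json.loads(s))

    def dump_raster_csv(self, path) -> None:
        np.savetxt(path, self.patch_ids.T, fmt="%d", delimiter=",")


def build_landscape(
    width_m: int,
    height_m: int,
    habitat_fraction: float,
    n_patches: int,
    cell_size_m: int = 1,
) -> Landscape:
    """Build a landscape with ``n_patches`` congruent square habitat patches.

    The patches are centred on a uniform k x k lattice (k = sqrt(n_patches)):
    patch (i, j) is a square of side ``s`` cells whose lower-left corner is at
    ``round((j + 0.5) * W / k - s / 2)`` where ``s = round(sqrt(T / n))`` and
    ``T = round(W * H * habitat_fraction)`` is the target habitat cell count.
    The realised habitat area therefore matches the target up to the rounding
    of the patch side.

    Raises
    ------
    ValueError
        If ``n_patches`` is not a perfect square, ``habitat_fraction`` is not
        in (0, 1), or the patches would be smaller than one cell or overlap.
    """
    k = math.isqrt(n_patches)
    if k * k != n_patches or n_patches < 1:
        raise ValueError(f"n_patches must be a perfect square >= 1, got {n_patches}")
    if not 0.0 < habitat_fraction < 1.0:
        raise ValueError(f"habitat_fraction must be in (0, 1), got {habitat_fraction}")
    W = width_m // cell_size_m
    H = height_m // cell_size_m
    total_cells = W * H
    target = round(total_cells * habitat_fraction)
    per_patch = target / n_patches
    side = round(math.sqrt(per_patch))
    if side < 1:
        raise ValueError(
            f"patch side would be < 1 cell ({per_patch:.3f} cells per patch); "
            "use a larger habitat fraction, fewer patches or smaller cells"
        )
    if side > min(W, H) // k:
        raise ValueError("patches would overlap or exceed the landscape")
    habitat = np.zeros((W, H), dtype=np.uint8)
    patch_ids = np.full((W, H), -1, dtype=np.int32)
    pid = 0
    for i in range(k):
        for j in range(k):
            cx = (j + 0.5) * W / k
            cy = (i + 0.5) * H / k
            x0 = int(round(cx - side / 2))
            y0 = int(round(cy - side / 2))
            habitat[x0 : x0 + side, y0 : y0 + side] = OPTIMAL
            patch_ids[x0 : x0 + side, y0 : y0 + side] = pid
            pid += 1
    return Landscape(
        width_m=width_m,
        height_m=height_m,
        habitat_fraction=habitat_fraction,
        n_patches=n_patches,
        cell_size_m=cell_size_m,
        habitat=habitat,
        patch_ids=patch_ids,
    )


def habitat_at(landscape: Landscape, x: int, y: int) -> int:
    """Habitat class (OPTIMAL or MATRIX) of cell (x, y); out of bounds rejects."""
    if not landscape.in_bounds(x, y):
        raise ValueError(f"cell ({x}, {y}) out of bounds")
    return int(landscape.habitat[x, y])


def patch_occupancy(
    landscape: Landscape, vole_positions: Iterable[Sequence[int]] | np.ndarray
) -> float:
    """Fraction of habitat patches containing at least one vole.

    ``vole_positions`` is an iterable of (x, y) cell coordinates (matrix
    positions are allowed and simply count toward no patch).  The unoccupied
    fraction reported in fragmentation diagnostics is ``1 - patch_occupancy``.
    """
    pos = np.asarray(list(vole_positions) if not isinstance(vole_positions, np.ndarray) else vole_positions)
    if pos.size == 0:
        return 0.0
    x, y = pos[:, 0].astype(int), pos[:, 1].astype(int)
    if (x < 0).any() or (y < 0).any() or (x >= landscape.width_cells).any() or (
        y >= landscape.height_cells
    ).any():
        raise ValueError("vole position out of bounds")
    pids = landscape.patch_ids[x, y]
    occupied = np.unique(pids[pids >= 0])
    return occupied.size / landscape.n_patches
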