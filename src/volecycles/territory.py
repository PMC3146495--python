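"""Occupancy bookkeeping for square territories on the cell grid.

Territories are axis-aligned squares identified by their centre cell.  Two
same-class territories of side ``s`` overlap by more than 50 % iff their
centres are closer than ``ceil(s / 2)`` in Chebyshev distance, and overlap at
all iff closer than ``s``; a :class:`TerritoryGrid` enforces a minimum
centre separation ``min_sep`` chosen accordingly (``ceil(s/2)`` for voles,
where >50 % overlap triggers eviction, ``s`` for predators, where no overlap
is tolerated).

The grid keeps three rasters updated incrementally:

* ``block`` — number of existing centres within Chebyshev distance
  ``min_sep - 1`` of each cell; a new centre may be placed only where this
  is zero.
* ``owner`` — territory holder id at its centre cell (-1 elsewhere).
* ``cover`` (optional) — number of territories whose square covers each
  cell; used for male-territory-over-female mating tests and for predator
  kill assignment via :class:`~volecycles.predators.PredatorGroup`'s variant.
"""

from __future__ import annotations

import math

import numpy as np


def _win(c: int, lo: int, hi: int, n: int) -> slice:
    return slice(max(c + lo, 0), min(c + hi, n - 1) + 1)


class TerritoryGrid:
    def __init__(
        self,
        width: int,
        height: int,
        side: int,
        min_sep: int | None = None,
        track_cover: bool = False,
    ):
        if side < 1:
            raise ValueError("territory side must be >= 1 cell")
        self.W, self.H = width, height
        self.side = side
        self.min_sep = min_sep if min_sep is not None else max(1, math.ceil(side / 2))
        self.rb = self.min_sep - 1  # block window radius
        self.lo = -(side // 2)      # cover window bounds (handles even sides)
        self.hi = self.lo + side - 1
        self.block = np.zeros((width, height), dtype=np.int16)
        self.owner = np.full((width, height), -1, dtype=np.int32)
        self.cover = np.zeros((width, height), dtype=np.int16) if track_cover else None
        # centres must keep the whole square inside the grid
        self.margin = np.zeros((width, height), dtype=bool)
        self.margin[-self.lo : width - self.hi, -self.lo : height - self.hi] = True
        self.n_owned = 0

    def can_place(self, x: int, y: int) -> bool:
        if not (0 <= x < self.W and 0 <= y < self.H):
            return False
        return bool(self.margin[x, y]) and self.block[x, y] == 0

    def valid_mask(self, base_ok: np.ndarray) -> np.ndarray:
        """Cells where a new centre may be placed, given a habitat mask."""
        return base_ok & self.margin & (self.block == 0)

    def place(self, idx: int, x: int, y: int) -> None:
        if not self.can_place(x, y):
            raise ValueError(f"cannot place territory at ({x}, {y})")
        self.block[_win(x, -self.rb, self.rb, self.W), _win(y, -self.rb, self.rb, self.H)] += 1
        self.owner[x, y] = idx
        if self.cover is not None:
            self.cover[_win(x, self.lo, self.hi, self.W), _win(y, self.lo, self.hi, self.H)] += 1
        self.n_owned += 1

    def remove(self, x: int, y: int) -> None:
        if self.owner[x, y] < 0:
            raise ValueError(f"no territory centred at ({x}, {y})")
        self.block[_win(x, -self.rb, self.rb, self.W), _win(y, -self.rb, self.rb, self.H)] -= 1
        self.owner[x, y] = -1
        if self.cover is not None:
            self.cover[_win(x, self.lo, self.hi, self.W), _win(y, self.lo, self.hi, self.H)] -= 1
        self.n_owned -= 1

    def square_slices(self, x: int, y: int) -> tuple[slice, slice]:
        return (_win(x, self.lo, self.hi, self.W), _win(y, self.lo, self.hi, self.H))


class SiteSearch:
    """Batch nearest-valid-cell queries within a fixed Chebyshev radius.

    Offsets are scanned in order of increasing Euclidean distance (ties by a
    fixed deterministic ordering) so the returned site is the nearest valid
    cell to each query point, making territory search reproducible given the
    daily agent schedule.
    """

    def __init__(self, radius: int):
        self.R = radius
        d = np.arange(-radius, radius + 1)
        dx, dy = np.meshgrid(d, d, indexing="ij")
        dx, dy = dx.ravel(), dy.ravel()
        order = np.lexsort((dy, dx, dx * dx + dy * dy))
        self.dx, self.dy = dx[order], dy[order]
        self._flat_cache: int | None = None

    def _pad(self, grid: np.ndarray) -> np.ndarray:
        R = self.R
        out = np.zeros((grid.shape[0] + 2 * R, grid.shape[1] + 2 * R), dtype=bool)
        out[R:-R, R:-R] = grid
        return out

    def _flat_offsets(self, padded_height: int) -> np.ndarray:
        if self._flat_cache != padded_height:
            self._off = (self.dx * padded_height + self.dy).astype(np.int64)
            self._flat_cache = padded_height
        return self._off

    def query(
        self,
        valid: np.ndarray,
        xs: np.ndarray,
        ys: np.ndarray,
        prefer: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest valid cell to each (x, y); prefers cells where ``prefer`` is
        true when any such valid cell is in range.

        Returns (cx, cy, found); cx/cy are undefined where found is False.
        """
        if xs.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, np.empty(0, dtype=bool)
        R = self.R
        vp = self._pad(valid)
        ph = vp.shape[1]
        off = self._flat_offsets(ph)
        base = (xs.astype(np.int64) + R) * ph + (ys.astype(np.int64) + R)
        idx = base[:, None] + off
        cand = vp.ravel().take(idx)
        if prefer is not None:
            pp = self._pad(prefer)
            pref = cand & pp.ravel().take(idx)
            has_pref = pref.any(axis=1)
            use = np.where(has_pref[:, None], pref, cand)
        else:
            use = cand
        first = use.argmax(axis=1)
        found = use[np.arange(xs.size), first]
        cx = xs + self.dx[first]
        cy = ys + self.dy[first]
        return cx, cy, found
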