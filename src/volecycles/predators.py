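"""Specialist and generalist predator agents.

Each predator holds a square hunting territory; no overlap is tolerated
between territories of the same type.  Hunting is confined to the territory:
each day every vole inside it is killed independently with the type's kill
efficiency.  A run of days without a successful kill triggers dispersal to a
new non-overlapping territory within the maximum dispersal distance.
Survival is evaluated once a year from the annual kill count, and surviving
predators reproduce in spring, producing ``floor(previous year's kills /
reproductive_threshold)`` offspring which are recruited only where a
non-overlapping territory (touching optimal habitat) fits near the parent.

Specialists (low reproductive threshold, high survival threshold) thereby
track vole density with a one-year lag — the delayed numerical response that
generates delayed density dependence — while generalists (high reproductive
threshold, low survival threshold) exert a nearly constant pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PredatorParams, PredatorType
from .landscape import Landscape
from .territory import TerritoryGrid
from .voles import Territory


@dataclass
class Predator:
    id: int
    ptype: PredatorType
    params: PredatorParams
    territory: Territory
    kills_this_year: int = 0
    prev_year_kills: int = 0
    failure_streak_days: int = 0
    alive: bool = True


def territory_side_cells(params: PredatorParams, cell_size_m: int) -> int:
    return max(1, round(math.sqrt(params.territory_size_m2) / cell_size_m))


def _overlaps_any(t: Territory, others: list[Predator]) -> bool:
    return any(
        o.alive and o.territory.overlap_area(t) > 0 for o in others
    )


def hunt(
    predator: Predator, voles_in_territory: list[int], rng: np.random.Generator
) -> list[int]:
    """One day's hunting within the territory.

    Each vole present is at risk with probability ``kill_efficiency``, but a
    predator handles at most one prey per day: the hunt succeeds with
    probability 1 - (1 - kill_efficiency)^n and the victim is the first vole
    caught in schedule order.  The day counts as a failure (for the
    dispersal streak) iff no vole was killed.  Updates the annual kill count
    and the failure streak; returns the killed vole ids (empty or one).
    """
    if not predator.alive:
        raise ValueError("dead predators do not hunt")
    killed: list[int] = []
    for vid in voles_in_territory:
        if rng.random() < predator.params.kill_efficiency:
            killed.append(vid)
            break
    predator.kills_this_year += len(killed)
    if killed:
        predator.failure_streak_days = 0
    else:
        predator.failure_streak_days += 1
    return killed


def maybe_disperse(
    predator: Predator,
    landscape: Landscape,
    others: list[Predator],
    rng: np.random.Generator,
    n_tries: int = 30,
) -> bool:
    """Relocate the territory after too many consecutive failure days.

    A new centre is drawn uniformly within the maximum dispersal distance
    (Chebyshev, in cells); the move happens only to a site whose territory
    fits in the landscape without overlapping any same-type territory.  If no
    valid site is found in ``n_tries`` draws the predator stays and retries
    the next day.  The annual kill count carries over across moves.
    """
    if predator.failure_streak_days < predator.params.failures_before_dispersal:
        return False
    side = predator.territory.side
    reach = max(1, int(predator.params.max_dispersal_m // landscape.cell_size_m))
    lo = -(side // 2)
    hi = lo + side - 1
    W, H = landscape.width_cells, landscape.height_cells
    for _ in range(n_tries):
        cx = predator.territory.cx + int(rng.integers(-reach, reach + 1))
        cy = predator.territory.cy + int(rng.integers(-reach, reach + 1))
        if not (-lo <= cx <= W - 1 - hi and -lo <= cy <= H - 1 - hi):
            continue
        t = Territory(cx, cy, side)
        if _overlaps_any(t, [o for o in others if o is not predator and o.ptype == predator.ptype]):
            continue
        predator.territory = t
        predator.failure_streak_days = 0
        return True
    return False


def annual_survival(predator: Predator) -> bool:
    """Year-end evaluation: survive iff the annual kill count reached the
    survival threshold; the counter is archived and reset either way."""
    predator.prev_year_kills = predator.kills_this_year
    predator.kills_this_year = 0
    if predator.prev_year_kills < predator.params.survival_threshold:
        predator.alive = False
    return predator.alive


def spring_reproduction(
    predator: Predator,
    landscape: Landscape,
    others: list[Predator],
    rng: np.random.Generator,
    next_id: int = 0,
    n_tries: int = 30,
) -> list[Predator]:
    """Spring recruitment: floor(previous year's kills / reproductive
    threshold) offspring, each placed in a non-overlapping territory within
    the parent's dispersal range or discarded if no site fits."""
    if not predator.alive:
        return []
    n_off = predator.prev_year_kills // predator.params.reproductive_threshold
    side = predator.territory.side
    reach = max(1, int(predator.params.max_dispersal_m // landscape.cell_size_m))
    lo = -(side // 2)
    hi = lo + side - 1
    W, H = landscape.width_cells, landscape.height_cells
    offspring: list[Predator] = []
    same_type = [o for o in others if o.ptype == predator.ptype] + [predator]
    for k in range(n_off):
        for _ in range(n_tries):
            cx = predator.territory.cx + int(rng.integers(-reach, reach + 1))
            cy = predator.territory.cy + int(rng.integers(-reach, reach + 1))
            if not (-lo <= cx <= W - 1 - hi and -lo <= cy <= H - 1 - hi):
                continue
            t = Territory(cx, cy, side)
            if _overlaps_any(t, same_type + offspring):
                continue
            child = Predator(
                id=next_id + len(offspring), ptype=predator.ptype,
                params=predator.params, territory=t,
            )
            offspring.append(child)
            break
    return offspring


class PredatorGroup:
    """Array-based community of one predator type, used by the engine.

    Applies exactly the rules of the per-predator operations above, but
    vectorised: kill assignment goes through an owner raster (well defined
    because same-type territories are disjoint) and spacing through a
    :class:`TerritoryGrid` with ``min_sep = side`` (zero overlap).
    Territories must touch at least one cell of optimal habitat.
    """

    def __init__(
        self,
        ptype: PredatorType,
        params: PredatorParams,
        landscape: Landscape,
        dispersal_scale: float = 1.0,
        max_kills_per_day: int = 1,
        habitat_fidelity: float = 0.5,
    ):
        self.ptype = ptype
        self.params = params
        self.landscape = landscape
        self.side = territory_side_cells(params, landscape.cell_size_m)
        self.reach = max(
            1, int(params.max_dispersal_m * dispersal_scale // landscape.cell_size_m)
        )
        self.max_kills_per_day = max_kills_per_day
        # probability that a failure-driven relocation insists on settling on
        # optimal habitat; otherwise the destination is unbiased, letting
        # predators drift off prey ground when hunting keeps failing
        self.habitat_fidelity = habitat_fidelity
        self.grid = TerritoryGrid(
            landscape.width_cells, landscape.height_cells, self.side, min_sep=self.side
        )
        # cover-owner raster: index of the predator whose (disjoint) territory
        # covers each cell, -1 where none; maintained incrementally.
        self.cov = np.full((self.grid.W, self.grid.H), -1, dtype=np.int32)
        self.cx = np.empty(0, dtype=np.int32)
        self.cy = np.empty(0, dtype=np.int32)
        self.alive = np.empty(0, dtype=bool)
        self.kills = np.empty(0, dtype=np.int64)
        self.prev_kills = np.empty(0, dtype=np.int64)
        self.streak = np.empty(0, dtype=np.int32)
        self.zero_kill_days = np.empty(0, dtype=np.int64)

    # -- population bookkeeping -------------------------------------------
    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def _append(self, cx: int, cy: int) -> None:
        idx = self.cx.size
        self.cx = np.append(self.cx, np.int32(cx))
        self.cy = np.append(self.cy, np.int32(cy))
        self.alive = np.append(self.alive, True)
        self.kills = np.append(self.kills, 0)
        self.prev_kills = np.append(self.prev_kills, 0)
        self.streak = np.append(self.streak, 0)
        self.zero_kill_days = np.append(self.zero_kill_days, 0)
        self.grid.place(idx, cx, cy)
        sx, sy = self.grid.square_slices(cx, cy)
        self.cov[sx, sy] = idx

    def _site_ok(self, cx: int, cy: int, require_habitat: bool = True) -> bool:
        """Settlement requires the centre cell on optimal habitat, so new
        territories genuinely cover prey ground; failure-driven dispersal
        (require_habitat=False) is unconstrained."""
        if not self.grid.can_place(cx, cy):
            return False
        if not require_habitat:
            return True
        return bool(self.landscape.habitat[cx, cy])

    def seed_initial(self, n: int, rng: np.random.Generator, n_tries: int = 200) -> None:
        W, H = self.landscape.width_cells, self.landscape.height_cells
        for _ in range(n):
            for _ in range(n_tries):
                cx = int(rng.integers(0, W))
                cy = int(rng.integers(0, H))
                if self._site_ok(cx, cy):
                    self._append(cx, cy)
                    break

    def compact(self) -> None:
        keep = np.flatnonzero(self.alive)
        remap = {old: new for new, old in enumerate(keep)}
        for name in ("cx", "cy", "alive", "kills", "prev_kills", "streak", "zero_kill_days"):
            setattr(self, name, getattr(self, name)[keep])
        # repaint the owner and cover rasters with the new indices
        mask = self.grid.owner >= 0
        self.grid.owner[mask] = np.array(
            [remap[o] for o in self.grid.owner[mask]], dtype=np.int32
        )
        self.cov[:] = -1
        for i in np.flatnonzero(self.alive):
            sx, sy = self.grid.square_slices(int(self.cx[i]), int(self.cy[i]))
            self.cov[sx, sy] = i

    # -- daily and annual steps -------------------------------------------
    def owner_of_cells(self, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
        """Index of the predator whose territory covers each cell (-1 none)."""
        return self.cov[vx, vy]

    def hunt_step(
        self, vx: np.ndarray, vy: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, int]:
        """Daily hunt over all voles; returns (killed_mask, n_exposed)."""
        n = self.cx.size
        if n == 0 or vx.size == 0:
            if n:
                self.streak[self.alive] += 1
                self.zero_kill_days[self.alive] += 1
            return np.zeros(vx.size, dtype=bool), 0
        owner = self.cov[vx, vy]
        exposed = owner >= 0
        killed = np.zeros(vx.size, dtype=bool)
        if exposed.any():
            eidx = np.flatnonzero(exposed)
            draws = rng.random(eidx.size)
            caught = draws < self.params.kill_efficiency
            if caught.any():
                # handling capacity: at most max_kills_per_day prey per
                # predator; victims are those with the smallest draws
                cidx = eidx[caught]
                own = owner[cidx]
                key = draws[caught]
                order = np.lexsort((key, own))
                own_sorted = own[order]
                newgrp = np.ones(own_sorted.size, dtype=bool)
                newgrp[1:] = own_sorted[1:] != own_sorted[:-1]
                # rank of each caught vole within its predator's day
                rank = np.arange(own_sorted.size) - np.maximum.accumulate(
                    np.where(newgrp, np.arange(own_sorted.size), 0)
                )
                take = rank < self.max_kills_per_day
                killed[cidx[order[take]]] = True
        counts = np.bincount(owner[killed], minlength=n)
        self.kills += counts
        success = counts > 0
        self.streak[self.alive & success] = 0
        self.streak[self.alive & ~success] += 1
        self.zero_kill_days[self.alive & ~success] += 1
        return killed, int(exposed.sum())

    def dispersal_step(self, rng: np.random.Generator, n_tries: int = 30) -> int:
        """Relocate every predator whose failure streak reached the threshold."""
        moved = 0
        for i in np.flatnonzero(
            self.alive & (self.streak >= self.params.failures_before_dispersal)
        ):
            ox, oy = int(self.cx[i]), int(self.cy[i])
            self.grid.remove(ox, oy)
            osx, osy = self.grid.square_slices(ox, oy)
            self.cov[osx, osy] = -1
            placed = False
            # a failing predator resettles on optimal habitat with
            # probability habitat_fidelity (falling back to any free site);
            # otherwise it drifts without assessing habitat
            passes = (
                (True, False)
                if rng.random() < self.habitat_fidelity
                else (False,)
            )
            for require_habitat in passes:
                for _ in range(n_tries):
                    cx = ox + int(rng.integers(-self.reach, self.reach + 1))
                    cy = oy + int(rng.integers(-self.reach, self.reach + 1))
                    if self._site_ok(cx, cy, require_habitat):
                        self.grid.place(int(i), cx, cy)
                        sx, sy = self.grid.square_slices(cx, cy)
                        self.cov[sx, sy] = i
                        self.cx[i], self.cy[i] = cx, cy
                        self.streak[i] = 0
                        moved += 1
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                self.grid.place(int(i), ox, oy)  # stay; retry tomorrow
                self.cov[osx, osy] = i
        return moved

    def year_end(self) -> dict:
        """Survival evaluation and annual diagnostics; resets counters."""
        alive_now = self.alive.copy()
        diag = {
            "n_predators": int(alive_now.sum()),
            "mean_zero_kill_days": (
                float(self.zero_kill_days[alive_now].mean()) if alive_now.any() else float("nan")
            ),
            "total_kills": int(self.kills[alive_now].sum()),
        }
        dead = alive_now & (self.kills < self.params.survival_threshold)
        for i in np.flatnonzero(dead):
            self.grid.remove(int(self.cx[i]), int(self.cy[i]))
            sx, sy = self.grid.square_slices(int(self.cx[i]), int(self.cy[i]))
            self.cov[sx, sy] = -1
        self.alive[dead] = False
        self.prev_kills = self.kills.copy()
        self.kills[:] = 0
        self.zero_kill_days[:] = 0
        return diag

    def spring_step(self, rng: np.random.Generator, max_attempts: int = 50) -> int:
        """Spring recruitment from the previous year's kills."""
        recruits = 0
        for i in np.flatnonzero(self.alive):
            n_off = int(self.prev_kills[i]) // self.params.reproductive_threshold
            ox, oy = int(self.cx[i]), int(self.cy[i])
            attempts = 0
            for _ in range(n_off):
                placed = False
                while attempts < max_attempts and not placed:
                    attempts += 1
                    cx = ox + int(rng.integers(-self.reach, self.reach + 1))
                    cy = oy + int(rng.integers(-self.reach, self.reach + 1))
                    if self._site_ok(cx, cy):
                        self._append(cx, cy)
                        recruits += 1
                        placed = True
                if not placed and attempts >= max_attempts:
                    break
        if self.cx.size > 4 * max(self.n_alive, 8):
            self.compact()
        return recruits
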