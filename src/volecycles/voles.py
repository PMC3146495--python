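"""Field-vole agents and their behavioural rules.

This module defines the individual-level rules — weaning, territory
assessment and acquisition, same-sex eviction, mate choice, breeding-season
gating, infanticide and mortality — operating on :class:`Vole` records and a
shared :class:`~volecycles.territory.TerritoryGrid`.  The engine applies the
same rules in vectorised form over its agent arrays; the functions here are
the reference semantics and are also usable for small constructed worlds.

Life stages: a vole enters the simulation when weaned at 14 days at its
mother's nest, with sex assigned with equal probability, and immediately
begins searching for a territory.  A territory (a square of optimal habitat)
is required for breeding.  Mature males assessing sites in the breeding
season prefer sites whose territory would overlap mature females.  Deaths
are due to predation, starvation after too many consecutive days in matrix
habitat, or reaching the physiological lifespan limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import BreedingSeason, VoleParams
from .landscape import OPTIMAL, Landscape
from .territory import SiteSearch, TerritoryGrid


@dataclass
class Territory:
    """Axis-aligned square territory: centre cell plus side length in cells."""

    cx: int
    cy: int
    side: int

    @property
    def area(self) -> int:
        return self.side * self.side

    def bounds(self) -> tuple[int, int, int, int]:
        lo = -(self.side // 2)
        hi = lo + self.side - 1
        return self.cx + lo, self.cy + lo, self.cx + hi, self.cy + hi

    def contains(self, x: int, y: int) -> bool:
        x0, y0, x1, y1 = self.bounds()
        return x0 <= x <= x1 and y0 <= y <= y1

    def overlap_area(self, other: "Territory") -> int:
        ax0, ay0, ax1, ay1 = self.bounds()
        bx0, by0, bx1, by1 = other.bounds()
        w = min(ax1, bx1) - max(ax0, bx0) + 1
        h = min(ay1, by1) - max(ay0, by0) + 1
        return max(w, 0) * max(h, 0)


@dataclass
class Vole:
    id: int
    sex: str  # "F" or "M"
    age_days: int
    x: int
    y: int
    territory: Territory | None = None
    mother_id: int | None = None
    unweaned_young: list[int] = field(default_factory=list)  # ages of litter
    alive: bool = True
    days_in_matrix: int = 0

    def stage(self, params: VoleParams) -> str:
        if self.age_days < params.maturation_age:
            return "JUVENILE"
        return "ADULT_F" if self.sex == "F" else "ADULT_M"


def in_breeding_season(day_of_year: int, season: BreedingSeason) -> bool:
    """True on days within [season.start, season.end] (inclusive)."""
    return season.start <= day_of_year <= season.end


def wean_litter(
    mother: Vole,
    landscape: Landscape,
    rng: np.random.Generator,
    params: VoleParams,
    next_id: int = 0,
) -> list[Vole]:
    """Weanlings entering the simulation at the mother's nest at age 14 days.

    Sex is assigned with probability 0.5 each (even sex ratio).  A dead
    mother's litter dies with her and yields no agents.
    """
    if not mother.alive:
        return []
    n = len(mother.unweaned_young)
    young = []
    for i in range(n):
        sex = "F" if rng.random() < 0.5 else "M"
        young.append(
            Vole(
                id=next_id + i,
                sex=sex,
                age_days=params.weaning_age,
                x=mother.x,
                y=mother.y,
                mother_id=mother.id,
            )
        )
    mother.unweaned_young = []
    return young


def assess_and_acquire_territory(
    vole: Vole,
    landscape: Landscape,
    grid: TerritoryGrid,
    params: VoleParams,
    female_presence: np.ndarray | None = None,
    in_season: bool = False,
) -> Territory | None:
    """Try to claim the nearest free square of optimal habitat.

    ``grid`` is the same-sex territory grid; the claimed site must be optimal
    habitat, keep the square inside the landscape, and respect the minimum
    centre separation implied by the >50 % overlap rule.  Mature males in the
    breeding season prefer sites from which their territory would overlap
    mature females (``female_presence`` marks such centre cells).  Returns the
    territory (already registered on the grid) or None, in which case the
    vole remains itinerant.
    """
    if not vole.alive:
        raise ValueError("dead voles do not assess territories")
    radius = max(1, params.search_radius_m // landscape.cell_size_m)
    search = SiteSearch(radius)
    valid = grid.valid_mask(landscape.habitat == OPTIMAL)
    prefer = None
    if (
        in_season
        and vole.sex == "M"
        and vole.age_days >= params.maturation_age
        and female_presence is not None
    ):
        prefer = female_presence
    cx, cy, found = search.query(
        valid, np.array([vole.x]), np.array([vole.y]), prefer=prefer
    )
    if not found[0]:
        return None
    grid.place(vole.id, int(cx[0]), int(cy[0]))
    t = Territory(int(cx[0]), int(cy[0]), grid.side)
    vole.territory = t
    vole.x, vole.y = t.cx, t.cy
    vole.days_in_matrix = 0
    return t


def resolve_eviction(older: Vole, younger: Vole) -> bool:
    """Evict the younger of two same-sex voles whose territories overlap > 50 %.

    Overlap is measured as shared area / area of the younger's territory; at
    exactly 50 % nothing happens (strict inequality).  Returns True if the
    younger vole lost its territory and entered dispersal.
    """
    if older.sex != younger.sex:
        return False
    if older.territory is None or younger.territory is None:
        return False
    if older.age_days <= younger.age_days:
        return False
    frac = younger.territory.overlap_area(older.territory) / younger.territory.area
    if frac > 0.5:
        younger.territory = None
        return True
    return False


def select_mate(female: Vole, males: list[Vole]) -> Vole | None:
    """The nearest male whose territory overlaps the female's position."""
    candidates = [
        m
        for m in males
        if m.alive and m.territory is not None and m.territory.contains(female.x, female.y)
    ]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda m: (math.hypot(m.x - female.x, m.y - female.y), m.id),
    )


def infanticide_success_prob(
    litter_age: int, p0: float = 0.5, weaning_age: int = 14
) -> float:
    """Success probability of an infanticide attempt, waning linearly with
    litter age from p0 at birth to 0 at weaning."""
    return p0 * max(0.0, 1.0 - litter_age / weaning_age)


def attempt_infanticide(
    male: Vole,
    female: Vole,
    litter_age: int,
    rng: np.random.Generator,
    params: VoleParams,
) -> bool:
    """An infanticide attempt by a mature male encountered outside his
    original territory; returns True if the litter is killed."""
    if male.territory is not None and male.territory.contains(male.x, male.y):
        return False  # still within his own bounds: no attempt
    if not female.unweaned_young:
        return False
    p = infanticide_success_prob(litter_age, params.infanticide_p0, params.weaning_age)
    if rng.random() < p:
        female.unweaned_young = []
        return True
    return False


def vole_mortality(vole: Vole, predation_flag: bool, params: VoleParams) -> bool:
    """Apply the three mortality causes; returns True if the vole survives."""
    if predation_flag or vole.days_in_matrix > params.starvation_days or (
        vole.age_days >= params.lifespan_days
    ):
        vole.alive = False
    return vole.alive
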