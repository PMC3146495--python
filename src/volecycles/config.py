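"""Parameter sets and the factorial scenario design.

The simulator uses a 365-day calendar with no leap days; calendar days are
1-based (Jan 1 = 1).  The vole breeding season starts April 5 (day 95) and
ends Oct 1 (day 274) by default; the short and long seasons move the end
date to Sep 1 (day 244) and Nov 1 (day 305).

``VoleParams`` collects the vole demographic calibration constants.  The
behavioural rules (weaning at 14 days, even sex ratio, territory requirement
for breeding, >50 % same-sex overlap eviction, closest-male mating,
infanticide waning to zero at weaning, death by predation / starvation /
lifespan) are fixed model structure; the constants here (gestation length,
litter size, maturation age, lifespan, territory sides, movement and search
ranges, starvation threshold, infanticide success at birth) are calibration
values documented in docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum

APR_1 = 91
APR_5 = 95
SEP_1 = 244
OCT_1 = 274
NOV_1 = 305
YEAR_DAYS = 365


@dataclass(frozen=True)
class BreedingSeason:
    """Calendar window (inclusive, 1-based day-of-year) of vole reproduction."""

    start: int = APR_5
    end: int = OCT_1

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("breeding season start must precede end")


SEASONS = {
    "SHORT": BreedingSeason(APR_5, SEP_1),
    "INTERMEDIATE": BreedingSeason(APR_5, OCT_1),
    "LONG": BreedingSeason(APR_5, NOV_1),
}


@dataclass(frozen=True)
class VoleParams:
    """Vole demographic calibration constants (lengths in metres, times in days)."""

    weaning_age: int = 14
    maturation_age: int = 30
    gestation_days: int = 21
    litter_min: int = 4
    litter_max: int = 6
    lifespan_days: int = 550
    female_territory_m: int = 10   # side of the female territory square
    male_territory_m: int = 30     # side of the male territory square
    movement_m_per_day: int = 50   # directed dispersal step for itinerant voles
    search_radius_m: int = 50      # radius scanned for a free territory site
    forage_radius_m: int = 20      # daily foraging excursion around the territory
    starvation_days: int = 14      # matrix days tolerated before starvation
    infanticide_p0: float = 0.5    # success probability against a newborn litter


class PredatorType(str, Enum):
    SPECIALIST = "SPECIALIST"
    GENERALIST = "GENERALIST"


@dataclass(frozen=True)
class PredatorParams:
    """Per-type predator life-history settings.

    ``reproductive_threshold``: voles killed per offspring produced in spring;
    ``survival_threshold``: voles per year needed to survive the year-end
    evaluation; ``territory_size_m2``: area of the square hunting territory;
    ``kill_efficiency``: daily probability of killing each vole inside the
    territory; ``failures_before_dispersal``: days without a kill before the
    predator relocates; ``max_dispersal_m``: maximum relocation distance.
    """

    reproductive_threshold: int
    survival_threshold: int
    territory_size_m2: float
    kill_efficiency: float
    failures_before_dispersal: int
    max_dispersal_m: float

    def __post_init__(self):
        if not 0.0 < self.kill_efficiency < 1.0:
            raise ValueError("kill_efficiency must be in (0, 1)")
        for name in (
            "reproductive_threshold",
            "survival_threshold",
            "territory_size_m2",
            "failures_before_dispersal",
            "max_dispersal_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


SPECIALIST = PredatorParams(
    reproductive_threshold=5,
    survival_threshold=90,
    territory_size_m2=2500.0,
    kill_efficiency=0.095,
    failures_before_dispersal=5,
    max_dispersal_m=500.0,
)

GENERALIST = PredatorParams(
    reproductive_threshold=90,
    survival_threshold=10,
    territory_size_m2=6400.0,
    kill_efficiency=0.04,
    failures_before_dispersal=20,
    max_dispersal_m=1000.0,
)

PREDATOR_DEFAULTS = {
    PredatorType.SPECIALIST: SPECIALIST,
    PredatorType.GENERALIST: GENERALIST,
}

ASSEMBLIES = ("GENERALIST_ONLY", "SPECIALIST_ONLY", "MIXED")
FRAGMENTATION_LEVELS = (1, 9, 25, 100)
SEASON_NAMES = ("SHORT", "INTERMEDIATE", "LONG")


def assembly_types(assembly: str) -> tuple[PredatorType, ...]:
    if assembly == "NONE":
        return ()  # predator-free world, outside the factorial design
    if assembly == "GENERALIST_ONLY":
        return (PredatorType.GENERALIST,)
    if assembly == "SPECIALIST_ONLY":
        return (PredatorType.SPECIALIST,)
    if assembly == "MIXED":
        return (PredatorType.SPECIALIST, PredatorType.GENERALIST)
    raise ValueError(f"unknown predator assembly {assembly!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the assembly x fragmentation x season factorial, plus run control.

    The full-scale design is a 10 x 10 km landscape at 1 m resolution with a
    100-year burn-in, 100 sampled years and 20 replicates; the defaults here
    are a scaled-down configuration (2.45 x 2.45 km at 10 m cells) whose
    habitat cell count divides exactly into 1/9/25/100 congruent square
    patches at 1.5 % habitat.
    """

    predator_assembly: str = "SPECIALIST_ONLY"
    n_patches: int = 1
    breeding_season: str = "INTERMEDIATE"
    width_m: int = 2450
    height_m: int = 2450
    habitat_fraction: float = 0.015
    cell_size_m: int = 10
    burn_in_years: int = 100
    sample_years: int = 100
    replicates: int = 20
    master_seed: int = 0
    vole_params: VoleParams = field(default_factory=VoleParams)
    census_day: int = OCT_1
    # spring immigration attempts per predator type, modelling the regional
    # pool around a desk-scale landscape; prevents absorbing predator
    # extinction in a closed world (set 0 for a fully closed system)
    predator_spring_immigrants: int = 2
    # predator dispersal distances are scaled with the landscape so that the
    # reach : patch-size ratio of the full 10 x 10 km design is preserved on
    # scaled-down landscapes; None derives the factor from the landscape size
    predator_dispersal_scale: float | None = None
    # daily prey-handling capacity per predator (kills per day)
    predator_max_kills_per_day: int = 2
    # probability that a failure-driven predator relocation targets habitat
    predator_habitat_fidelity: float = 0.15

    @property
    def dispersal_scale(self) -> float:
        if self.predator_dispersal_scale is not None:
            return self.predator_dispersal_scale
        return min(self.width_m, self.height_m) / 10000.0

    def __post_init__(self):
        assembly_types(self.predator_assembly)  # validate
        if self.n_patches not in FRAGMENTATION_LEVELS:
            raise ValueError(f"n_patches must be one of {FRAGMENTATION_LEVELS}")
        if self.breeding_season not in SEASONS:
            raise ValueError(f"breeding_season must be one of {tuple(SEASONS)}")

    @property
    def season(self) -> BreedingSeason:
        return SEASONS[self.breeding_season]

    @property
    def scenario_id(self) -> str:
        return f"{self.predator_assembly}_p{self.n_patches}_{self.breeding_season}"

    @property
    def scenario_index(self) -> int:
        a = (
            ASSEMBLIES.index(self.predator_assembly)
            if self.predator_assembly in ASSEMBLIES
            else len(ASSEMBLIES)  # e.g. the predator-free assembly
        )
        return (
            a * len(FRAGMENTATION_LEVELS) * len(SEASON_NAMES)
            + FRAGMENTATION_LEVELS.index(self.n_patches) * len(SEASON_NAMES)
            + SEASON_NAMES.index(self.breeding_season)
        )


def scenario_grid(base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """Enumerate the full 3 x 4 x 3 = 36 scenario factorial from a base config."""
    base = base or ScenarioConfig()
    return [
        replace(base, predator_assembly=a, n_patches=n, breeding_season=b)
        for a, n, b in itertools.product(ASSEMBLIES, FRAGMENTATION_LEVELS, SEASON_NAMES)
    ]
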