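"""Vole behavioural rules: weaning, territories, eviction, mating, mortality."""

import numpy as np
import pytest
from scipy import stats

from volecycles.config import SEASONS, BreedingSeason, VoleParams
from volecycles.landscape import build_landscape
from volecycles.territory import TerritoryGrid
from volecycles.voles import (
    Territory,
    Vole,
    assess_and_acquire_territory,
    attempt_infanticide,
    in_breeding_season,
    infanticide_success_prob,
    resolve_eviction,
    select_mate,
    vole_mortality,
    wean_litter,
)

P = VoleParams()


def make_land():
    return build_landscape(2450, 2450, 0.015, 1, 10)


def female(vid=0, age=60, x=120, y=120, terr=None):
    return Vole(id=vid, sex="F", age_days=age, x=x, y=y, territory=terr)


def male(vid=1, age=60, x=120, y=120, terr=None):
    return Vole(id=vid, sex="M", age_days=age, x=x, y=y, territory=terr)


class TestWeaning:
    def test_litter_placed_at_nest(self, rng):
        mum = female(terr=Territory(120, 120, 1))
        mum.unweaned_young = [14] * 4
        young = wean_litter(mum, make_land(), rng, P)
        assert len(young) == 4
        assert all(v.x == 120 and v.y == 120 and v.age_days == 14 for v in young)
        assert mum.unweaned_young == []

    def test_empty_litter(self, rng):
        mum = female()
        assert wean_litter(mum, make_land(), rng, P) == []

    def test_dead_mother_litter_dies(self, rng):
        mum = female()
        mum.alive = False
        mum.unweaned_young = [14] * 5
        assert wean_litter(mum, make_land(), rng, P) == []

    def test_even_sex_ratio(self, rng):
        mum = female()
        males = 0
        total = 10_000
        for _ in range(total // 5):
            mum.unweaned_young = [14] * 5
            males += sum(v.sex == "M" for v in wean_litter(mum, make_land(), rng, P))
        lo, hi = stats.binom.interval(0.99, total, 0.5)
        assert lo <= males <= hi


class TestTerritoryAcquisition:
    def test_lone_female_in_empty_patch(self):
        land = make_land()
        grid = TerritoryGrid(land.width_cells, land.height_cells, 1)
        v = female()
        t = assess_and_acquire_territory(v, land, grid, P)
        assert t is not None and land.habitat[t.cx, t.cy] == 1

    def test_surrounded_by_matrix(self):
        land = make_land()
        grid = TerritoryGrid(land.width_cells, land.height_cells, 1)
        v = female(x=2, y=2)  # far corner, all matrix within search range
        assert assess_and_acquire_territory(v, land, grid, P) is None

    def test_two_females_zero_overlap(self):
        land = make_land()
        grid = TerritoryGrid(land.width_cells, land.height_cells, 1)
        a, b = female(0), female(1)
        ta = assess_and_acquire_territory(a, land, grid, P)
        tb = assess_and_acquire_territory(b, land, grid, P)
        assert ta and tb and ta.overlap_area(tb) == 0


class TestEviction:
    def test_younger_evicted_above_half_overlap(self):
        old = female(0, age=200, terr=Territory(10, 10, 3))
        yng = female(1, age=50, terr=Territory(11, 10, 3))  # 6/9 = 67% overlap
        assert resolve_eviction(old, yng) is True
        assert yng.territory is None

    def test_exactly_half_no_eviction(self):
        # two 2x2 squares sharing a 2x1 strip: overlap 2/4 = 50%
        old = female(0, age=200, terr=Territory(10, 10, 2))
        yng = female(1, age=50, terr=Territory(11, 10, 2))
        assert yng.territory.overlap_area(old.territory) / yng.territory.area == 0.5
        assert resolve_eviction(old, yng) is False

    def test_opposite_sex_never_evicts(self):
        old = female(0, age=200, terr=Territory(10, 10, 3))
        yng = male(1, age=50, terr=Territory(10, 10, 3))  # 100% overlap
        assert resolve_eviction(old, yng) is False


class TestMateChoice:
    def test_single_overlapping_male(self):
        f = female(x=50, y=50)
        m = male(1, x=51, y=50, terr=Territory(51, 50, 3))
        assert select_mate(f, [m]) is m

    def test_closest_of_two(self):
        f = female(x=50, y=50)
        near = male(1, x=50, y=49, terr=Territory(50, 49, 3))
        far = male(2, x=51, y=51, terr=Territory(51, 51, 3))
        assert select_mate(f, [near, far]) is near

    def test_no_overlap_none(self):
        f = female(x=50, y=50)
        m = male(1, x=60, y=60, terr=Territory(60, 60, 3))
        assert select_mate(f, [m]) is None


class TestBreedingSeason:
    @pytest.mark.parametrize(
        "day,season,expected",
        [
            (95, "INTERMEDIATE", True),    # Apr 5
            (275, "INTERMEDIATE", False),  # Oct 2
            (288, "LONG", True),           # Oct 15, ends Nov 1
            (250, "SHORT", False),         # after Sep 1
        ],
    )
    def test_window(self, day, season, expected):
        assert in_breeding_season(day, SEASONS[season]) is expected

    def test_invalid_season_rejected(self):
        with pytest.raises(ValueError):
            BreedingSeason(200, 100)


class TestInfanticide:
    def test_weaned_litter_immune(self):
        assert infanticide_success_prob(14, p0=0.5) == 0.0

    def test_success_monotone_in_litter_age(self):
        probs = [infanticide_success_prob(a, p0=0.5) for a in range(15)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_male_inside_own_territory_no_attempt(self, rng):
        m = male(terr=Territory(120, 120, 3))
        f = female()
        f.unweaned_young = [2, 2, 2]
        assert attempt_infanticide(m, f, 2, rng, P) is False
        assert f.unweaned_young  # litter untouched

    def test_newborns_at_higher_risk(self, rng):
        kills = {0: 0, 10: 0}
        for age in kills:
            for _ in range(2000):
                m = male()  # itinerant: no territory
                f = female()
                f.unweaned_young = [age] * 4
                if attempt_infanticide(m, f, age, rng, P):
                    kills[age] += 1
        assert kills[0] > kills[10]


class TestMortality:
    def test_predation(self):
        v = female()
        assert vole_mortality(v, True, P) is False

    def test_lifespan_limit(self):
        v = female(age=P.lifespan_days)
        assert vole_mortality(v, False, P) is False

    def test_starvation(self):
        v = female()
        v.days_in_matrix = P.starvation_days + 1
        assert vole_mortality(v, False, P) is False

    def test_healthy_survives(self):
        v = female()
        assert vole_mortality(v, False, P) is True
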