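"""Predator rules: hunting, dispersal, annual survival, spring recruitment."""

import numpy as np
import pytest
from scipy import stats

from volecycles.config import GENERALIST, SPECIALIST, PredatorType
from volecycles.landscape import build_landscape
from volecycles.predators import (
    Predator,
    PredatorGroup,
    annual_survival,
    hunt,
    maybe_disperse,
    spring_reproduction,
    territory_side_cells,
)
from volecycles.voles import Territory


def make_land():
    return build_landscape(2450, 2450, 0.015, 1, 10)


def specialist(vid=0, cx=120, cy=120):
    side = territory_side_cells(SPECIALIST, 10)
    return Predator(id=vid, ptype=PredatorType.SPECIALIST, params=SPECIALIST,
                    territory=Territory(cx, cy, side))


def generalist(vid=0, cx=120, cy=120):
    side = territory_side_cells(GENERALIST, 10)
    return Predator(id=vid, ptype=PredatorType.GENERALIST, params=GENERALIST,
                    territory=Territory(cx, cy, side))


class TestHunt:
    def test_empty_territory_failure_day(self, rng):
        p = specialist()
        assert hunt(p, [], rng) == []
        assert p.failure_streak_days == 1 and p.kills_this_year == 0

    @pytest.mark.parametrize(
        "factory,eff", [(specialist, 0.095), (generalist, 0.04)]
    )
    def test_kill_rate_at_sparse_exposure(self, factory, eff, rng):
        # one vole-day per day for 2000 days: the handling cap never binds,
        # so the realised kill rate is the per-vole daily risk
        kills = 0
        for _ in range(2000):
            p = factory()
            kills += len(hunt(p, [42], rng))
        lo, hi = stats.binom.interval(0.99, 2000, eff)
        assert lo <= kills <= hi

    def test_at_most_one_kill_per_day(self, rng):
        p = specialist()
        assert len(hunt(p, list(range(500)), rng)) <= 1


class TestDispersal:
    def test_below_threshold_stays(self, rng):
        p = specialist()
        p.failure_streak_days = SPECIALIST.failures_before_dispersal - 1
        home = (p.territory.cx, p.territory.cy)
        assert maybe_disperse(p, make_land(), [], rng) is False
        assert (p.territory.cx, p.territory.cy) == home

    def test_moves_within_max_distance(self, rng):
        land = make_land()
        p = specialist()
        p.failure_streak_days = SPECIALIST.failures_before_dispersal
        home = (p.territory.cx, p.territory.cy)
        assert maybe_disperse(p, land, [], rng) is True
        reach = SPECIALIST.max_dispersal_m // land.cell_size_m
        assert abs(p.territory.cx - home[0]) <= reach
        assert abs(p.territory.cy - home[1]) <= reach
        assert p.failure_streak_days == 0

    def test_blocked_everywhere_stays(self, rng):
        # surround the disperser with same-type territories at every site
        land = build_landscape(300, 300, 0.5, 1, 10)  # tiny 30x30 world
        side = territory_side_cells(SPECIALIST, 10)
        p = specialist(0, 15, 15)
        others = [
            Predator(id=k + 1, ptype=PredatorType.SPECIALIST, params=SPECIALIST,
                     territory=Territory(cx, cy, side))
            for k, (cx, cy) in enumerate(
                (x, y) for x in range(2, 29, 5) for y in range(2, 29, 5)
            )
        ]
        p.failure_streak_days = 99
        assert maybe_disperse(p, land, others, rng, n_tries=50) is False


class TestAnnualSurvival:
    @pytest.mark.parametrize(
        "factory,kills,expected",
        [
            (specialist, 89, False),
            (specialist, 90, True),
            (generalist, 10, True),
            (generalist, 9, False),
        ],
    )
    def test_threshold_boundary(self, factory, kills, expected):
        p = factory()
        p.kills_this_year = kills
        assert annual_survival(p) is expected
        assert p.kills_this_year == 0 and p.prev_year_kills == kills


class TestSpringReproduction:
    def test_floor_rule(self, rng):
        p = specialist()
        p.prev_year_kills = 23
        off = spring_reproduction(p, make_land(), [], rng)
        assert len(off) <= 23 // 5
        assert len(off) >= 1  # plenty of space in an empty landscape

    def test_generalist_below_threshold_none(self, rng):
        p = generalist()
        p.prev_year_kills = 89
        assert spring_reproduction(p, make_land(), [], rng) == []

    def test_offspring_no_overlap(self, rng):
        p = specialist()
        p.prev_year_kills = 200
        off = spring_reproduction(p, make_land(), [], rng)
        all_preds = [p] + off
        for i, a in enumerate(all_preds):
            for b in all_preds[i + 1 :]:
                assert a.territory.overlap_area(b.territory) == 0


class TestPredatorGroup:
    def test_disjoint_territories_after_seed_and_disperse(self, rng):
        land = make_land()
        g = PredatorGroup(PredatorType.SPECIALIST, SPECIALIST, land)
        g.seed_initial(10, rng)
        assert g.n_alive > 1

        def assert_disjoint():
            idx = np.flatnonzero(g.alive)
            for i in idx:
                for j in idx:
                    if i < j:
                        dx = abs(int(g.cx[i]) - int(g.cx[j]))
                        dy = abs(int(g.cy[i]) - int(g.cy[j]))
                        assert max(dx, dy) >= g.side

        assert_disjoint()
        g.streak[:] = SPECIALIST.failures_before_dispersal
        g.dispersal_step(rng)
        assert_disjoint()

    def test_numerical_response_is_delayed(self, rng):
        """A prey pulse raises specialist numbers the following year, while
        generalists stay nearly unchanged."""
        land = make_land()
        rng2 = np.random.default_rng(1)
        out = {}
        for ptype, params in [
            (PredatorType.SPECIALIST, SPECIALIST),
            (PredatorType.GENERALIST, GENERALIST),
        ]:
            g = PredatorGroup(ptype, params, land)
            g.seed_initial(5, rng2)
            n0 = g.n_alive
            # year 1: prey stepped up to 4 voles inside every territory —
            # ample for the specialist's low reproductive threshold (5 kills
            # per offspring), far below the generalist's (90)
            live = np.flatnonzero(g.alive)
            vx = np.repeat(g.cx[live], 4)
            vy = np.repeat(g.cy[live], 4)
            for _ in range(365):
                g.hunt_step(vx, vy, rng2)
            g.year_end()
            g.spring_step(rng2)
            out[ptype] = (n0, g.n_alive)
        ns0, ns1 = out[PredatorType.SPECIALIST]
        ng0, ng1 = out[PredatorType.GENERALIST]
        assert ns1 > ns0  # delayed numerical response
        assert abs(ng1 - ng0) <= 1  # generalists barely respond
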