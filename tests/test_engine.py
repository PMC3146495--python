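"""Engine: determinism, daily-step invariants, conservation, diagnostics."""

import numpy as np
import pytest

from volecycles.config import GENERALIST, SPECIALIST, PredatorParams, PredatorType, ScenarioConfig, VoleParams
from volecycles.engine import F, M, World, replicate_rng, run_replicate
from volecycles.landscape import build_landscape
from volecycles.predators import PredatorGroup


def small_config(**kw):
    base = dict(
        predator_assembly="GENERALIST_ONLY",
        n_patches=1,
        width_m=1230,
        height_m=1230,
        burn_in_years=0,
        sample_years=3,
        replicates=1,
        master_seed=42,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = small_config()
        a = run_replicate(cfg, 0)
        b = run_replicate(cfg, 0)
        assert np.array_equal(a.series.counts, b.series.counts)
        assert a.diagnostics.equals(b.diagnostics)

    def test_replicates_differ(self):
        cfg = small_config()
        a = run_replicate(cfg, 0)
        b = run_replicate(cfg, 1)
        assert not np.array_equal(a.series.counts, b.series.counts)

    def test_master_seeds_differ(self):
        a = run_replicate(small_config(master_seed=1), 0)
        b = run_replicate(small_config(master_seed=2), 0)
        assert not np.array_equal(a.series.counts, b.series.counts)


class TestDailyStep:
    def test_empty_world_stays_empty(self):
        cfg = small_config(predator_assembly="NONE")
        w = World(cfg, replicate_rng(cfg, 0))
        w.voles.alive[:] = False
        for _ in range(30):
            w.daily_step()
        assert w.vole_count == 0

    def test_out_of_season_population_non_increasing(self):
        cfg = small_config(predator_assembly="NONE")
        w = World(cfg, replicate_rng(cfg, 0))
        # advance to deep winter (day 1 is Jan 1; season starts Apr 5)
        before = w.vole_count
        for _ in range(40):
            w.daily_step()
        assert w.vole_count <= before

    def test_death_causes_partition_population_change(self):
        cfg = small_config(predator_assembly="SPECIALIST_ONLY", sample_years=2)
        w = World(cfg, replicate_rng(cfg, 0))
        for _ in range(2 * 365):
            w.daily_step()
        a = w.audit
        deaths = (
            a["deaths_predation"] + a["deaths_starvation"] + a["deaths_lifespan"]
        )
        assert a["initial"] + a["births"] - deaths == w.vole_count

    def test_no_pregnancies_or_litters_survive_winter(self):
        cfg = small_config()
        w = World(cfg, replicate_rng(cfg, 0))
        for _ in range(365):
            w.daily_step()
        # at Jan 1 every litter conceived in season is weaned and no
        # pregnancy is ongoing (season ended Oct 1, gestation 21 d)
        v = w.voles
        alive = v.alive[: v.n]
        assert (v.preg[: v.n][alive] == -1).all()
        assert (v.lit_age[: v.n][alive] == -1).all()

    def test_same_sex_territories_never_conflict(self):
        cfg = small_config(predator_assembly="SPECIALIST_ONLY")
        w = World(cfg, replicate_rng(cfg, 0))
        for _ in range(200):
            w.daily_step()
        v = w.voles
        terr = np.flatnonzero(v.alive[: v.n] & v.has_terr[: v.n])
        fem = terr[v.sex[terr] == F]
        mal = terr[v.sex[terr] == M]
        fcells = set(zip(v.tx[fem].tolist(), v.ty[fem].tolist()))
        assert len(fcells) == fem.size  # one female territory per cell
        mpos = np.column_stack((v.tx[mal], v.ty[mal]))
        for i in range(mal.size):
            d = np.abs(mpos - mpos[i]).max(axis=1)
            d[i] = 99
            assert (d >= w.mgrid.min_sep).all()


class TestCarryingCapacity:
    def test_no_predators_territory_limited(self):
        """Without predation the female population settles near one territory
        per habitat cell (density dependence via competition for space)."""
        cfg = small_config(predator_assembly="NONE", sample_years=6)
        w = World(cfg, replicate_rng(cfg, 0))
        # measure at the end of the 6th breeding season (Oct 1); winter
        # lifespan deaths leave vacancies that refill only in spring
        for _ in range(5 * 365 + 274):
            w.daily_step()
        v = w.voles
        terr_f = int(
            (v.alive[: v.n] & v.has_terr[: v.n] & (v.sex[: v.n] == F)).sum()
        )
        capacity = w.land.n_habitat_cells  # one 10 m x 10 m territory per cell
        assert capacity * 0.75 <= terr_f <= capacity * 1.25


class TestDiagnostics:
    def test_no_predators_reported_missing(self):
        cfg = small_config(predator_assembly="NONE")
        w = World(cfg, replicate_rng(cfg, 0))
        d = w.diagnostics()
        assert "specialist_failure_day_fraction" not in d
        assert 0.0 <= d["patch_occupancy"] <= 1.0

    def test_three_day_hand_trace(self):
        """Drive one near-deterministic predator for three days and check the
        kill/streak/zero-kill-day bookkeeping against hand computation."""
        land = build_landscape(1230, 1230, 0.015, 1, 10)
        params = PredatorParams(
            reproductive_threshold=5, survival_threshold=90,
            territory_size_m2=2500.0, kill_efficiency=0.999999,
            failures_before_dispersal=5, max_dispersal_m=500.0,
        )
        g = PredatorGroup(PredatorType.SPECIALIST, params, land)
        rng = np.random.default_rng(0)
        # place the predator at the patch centre (deterministic)
        cells = np.argwhere(land.habitat)
        cx, cy = (int(c) for c in cells[len(cells) // 2])
        g._append(cx, cy)
        # day 1: five voles present -> one kill; day 2: none -> failure;
        # day 3: two voles -> one kill
        vday = [5, 0, 2]
        for k in vday:
            vx = np.full(k, cx)
            vy = np.full(k, cy)
            killed, exposed = g.hunt_step(vx, vy, rng)
            assert exposed == k
            assert killed.sum() == (1 if k else 0)
        assert int(g.kills[0]) == 2
        assert int(g.zero_kill_days[0]) == 1
        assert int(g.streak[0]) == 0  # reset by the day-3 success

    def test_failure_fraction_zero_with_daily_kills(self):
        cfg = small_config(predator_assembly="SPECIALIST_ONLY")
        w = World(cfg, replicate_rng(cfg, 0))
        g = w.groups[0]
        live = np.flatnonzero(g.alive)
        g.zero_kill_days[live] = 0
        w.day_of_year = 100
        d = w.diagnostics()
        assert d["specialist_failure_day_fraction"] == 0.0


class TestSeriesContract:
    def test_series_length_and_flags(self):
        cfg = small_config(burn_in_years=1, sample_years=2)
        res = run_replicate(cfg, 0)
        assert len(res.series.counts) == 2
        assert res.series.extinct == bool((res.series.counts == 0).any())
        assert (res.series.density_opt_ha >= 0).all()
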