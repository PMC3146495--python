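"""Daily scheduler, world state and scenario runner.

The world advances in one-day steps over a 365-day year.  Within a day the
order is: (1) vole behaviours — weaning, gestation, mating, territory
assessment/acquisition, dispersal movement, infanticide; (2) predator
hunting; (3) predator dispersal checks; (4) mortality.  Annual events are
the vole census (default Oct 1), predator survival evaluation (Dec 31) and
predator spring reproduction (Apr 1).

State is kept in flat numpy arrays (one row per vole) so that a daily step
is a fixed small number of vectorised operations plus short Python loops
over the few agents that change territory on any given day; a century of
simulated days for a scaled landscape runs in seconds to minutes.

Determinism: all randomness flows from one numpy Generator seeded from
(master_seed, scenario_index, replicate), so identical configurations
replay bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    APR_1,
    PREDATOR_DEFAULTS,
    YEAR_DAYS,
    ScenarioConfig,
    assembly_types,
)
from .landscape import OPTIMAL, Landscape, build_landscape, patch_occupancy
from .predators import PredatorGroup, territory_side_cells
from .territory import SiteSearch, TerritoryGrid
from .voles import in_breeding_season

F, M = 0, 1

# eight compass headings for directed itinerant movement
DIRS8 = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int32,
)


class VoleArrays:
    """Struct-of-arrays vole population with capacity doubling."""

    FIELDS = (
        ("alive", bool, False),
        ("sex", np.int8, 0),
        ("age", np.int32, 0),
        ("x", np.int32, 0),
        ("y", np.int32, 0),
        ("has_terr", bool, False),
        ("tx", np.int32, -1),
        ("ty", np.int32, -1),
        ("dmat", np.int16, 0),
        ("preg", np.int16, -1),       # days of gestation remaining; -1 = not pregnant
        ("lit_age", np.int16, -1),    # age of unweaned litter; -1 = none
        ("lit_size", np.int16, 0),
        ("heading", np.int8, 0),
    )

    def __init__(self, capacity: int = 1024):
        self.n = 0
        for name, dtype, _fill in self.FIELDS:
            setattr(self, name, np.zeros(capacity, dtype=dtype))

    @property
    def capacity(self) -> int:
        return self.alive.size

    def _grow(self, need: int) -> None:
        cap = self.capacity
        new = max(cap * 2, self.n + need)
        for name, dtype, fill in self.FIELDS:
            arr = np.full(new, fill, dtype=dtype)
            arr[: self.n] = getattr(self, name)[: self.n]
            setattr(self, name, arr)

    def add(self, xs, ys, sexes, ages, headings) -> np.ndarray:
        k = len(xs)
        if self.n + k > self.capacity:
            self._grow(k)
        sl = slice(self.n, self.n + k)
        idx = np.arange(self.n, self.n + k)
        self.alive[sl] = True
        self.sex[sl] = sexes
        self.age[sl] = ages
        self.x[sl] = xs
        self.y[sl] = ys
        self.has_terr[sl] = False
        self.tx[sl] = -1
        self.ty[sl] = -1
        self.dmat[sl] = 0
        self.preg[sl] = -1
        self.lit_age[sl] = -1
        self.lit_size[sl] = 0
        self.heading[sl] = headings
        self.n += k
        return idx

    def compact(self) -> np.ndarray:
        """Drop dead rows; returns the kept (old) indices in order."""
        keep = np.flatnonzero(self.alive[: self.n])
        for name, _dtype, _fill in self.FIELDS:
            arr = getattr(self, name)
            arr[: keep.size] = arr[keep]
            setattr(self, name, arr)
        self.n = keep.size
        return keep


@dataclass
class VoleTimeSeries:
    """Annual post-burn-in census series for one replicate of one scenario."""

    scenario_id: str
    replicate: int
    counts: np.ndarray
    density_opt_ha: np.ndarray    # voles per hectare of optimal habitat
    density_total_ha: np.ndarray  # voles per hectare of total landscape
    census_day: int
    extinct: bool


@dataclass
class RunResult:
    series: VoleTimeSeries
    diagnostics: pd.DataFrame = field(repr=False, default=None)


class World:
    def __init__(self, config: ScenarioConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.land: Landscape = build_landscape(
            config.width_m,
            config.height_m,
            config.habitat_fraction,
            config.n_patches,
            config.cell_size_m,
        )
        p = config.vole_params
        cs = config.cell_size_m
        W, H = self.land.width_cells, self.land.height_cells
        self.sf = max(1, round(p.female_territory_m / cs))
        self.sm = max(1, round(p.male_territory_m / cs))
        self.fgrid = TerritoryGrid(W, H, self.sf)
        self.mgrid = TerritoryGrid(W, H, self.sm, track_cover=True)
        self.search = SiteSearch(max(1, p.search_radius_m // cs))
        self.move_cells = max(1, p.movement_m_per_day // cs)
        # raster of "a male centred here would cover >= 1 female territory centre"
        self.fnear = np.zeros((W, H), dtype=np.int16)
        self.optimal = self.land.habitat == OPTIMAL
        # cells from which a territory search could possibly succeed: within
        # the search radius of some optimal cell (static; saves querying for
        # floaters deep in the matrix)
        from scipy.ndimage import binary_dilation

        R = self.search.R
        self.near_habitat = binary_dilation(
            self.optimal, structure=np.ones((2 * R + 1, 2 * R + 1), dtype=bool)
        )
        self.voles = VoleArrays()
        self.groups = [
            PredatorGroup(
                t, PREDATOR_DEFAULTS[t], self.land,
                dispersal_scale=config.dispersal_scale,
                max_kills_per_day=config.predator_max_kills_per_day,
                habitat_fidelity=config.predator_habitat_fidelity,
            )
            for t in assembly_types(config.predator_assembly)
        ]
        self.day_of_year = 0
        self.year = 0
        self.audit = {
            "initial": 0, "births": 0,
            "deaths_predation": 0, "deaths_starvation": 0, "deaths_lifespan": 0,
        }
        # optional verbose per-day census rows (date, stage counts, births,
        # deaths by cause); cheap enough to keep as plain dicts
        self.collect_daily = False
        self.daily_rows: list[dict] = []
        # per-year predator diagnostics accumulators, keyed by predator type
        self._diag_acc = {
            g.ptype.value: {"exposure_days": 0, "predator_days": 0}
            for g in self.groups
        }
        self._year_rows: list[dict] = []
        self._occupancy_at_census = float("nan")
        self._seed_world()

    # ------------------------------------------------------------------ init
    def _seed_world(self) -> None:
        rng = self.rng
        hab = np.argwhere(self.optimal)
        n_hab = hab.shape[0]
        # females on half the habitat cells, males on an eighth (spacing permitting)
        nf = n_hab // 2
        nm = n_hab // 8
        order = rng.permutation(n_hab)
        placed_f = 0
        v = self.voles
        for i in order:
            if placed_f >= nf:
                break
            cx, cy = int(hab[i, 0]), int(hab[i, 1])
            if self.optimal[cx, cy] and self.fgrid.can_place(cx, cy):
                idx = v.add([cx], [cy], [F], [int(rng.integers(60, 300))],
                            [int(rng.integers(0, 8))])[0]
                self._grant_territory(int(idx), cx, cy, F)
                placed_f += 1
        placed_m = 0
        for i in rng.permutation(n_hab):
            if placed_m >= nm:
                break
            cx, cy = int(hab[i, 0]), int(hab[i, 1])
            if self.optimal[cx, cy] and self.mgrid.can_place(cx, cy):
                idx = v.add([cx], [cy], [M], [int(rng.integers(60, 300))],
                            [int(rng.integers(0, 8))])[0]
                self._grant_territory(int(idx), cx, cy, M)
                placed_m += 1
        self.audit["initial"] = v.n
        for g in self.groups:
            n0 = max(2, self.land.n_habitat_cells // (g.side * g.side * 4))
            g.seed_initial(n0, rng)

    # ------------------------------------------------------- territory admin
    def _grant_territory(self, idx: int, cx: int, cy: int, sex: int) -> None:
        v = self.voles
        grid = self.fgrid if sex == F else self.mgrid
        grid.place(idx, cx, cy)
        v.has_terr[idx] = True
        v.tx[idx], v.ty[idx] = cx, cy
        v.x[idx], v.y[idx] = cx, cy
        v.dmat[idx] = 0
        if sex == F:
            self._bump_fnear(cx, cy, +1)

    def _release_territory(self, idx: int) -> None:
        v = self.voles
        cx, cy = int(v.tx[idx]), int(v.ty[idx])
        if v.sex[idx] == F:
            self.fgrid.remove(cx, cy)
            self._bump_fnear(cx, cy, -1)
        else:
            self.mgrid.remove(cx, cy)
        v.has_terr[idx] = False
        v.tx[idx] = v.ty[idx] = -1

    def _bump_fnear(self, fx: int, fy: int, delta: int) -> None:
        # a male centred at (x, y) covers cells [x+lo, x+hi]; he covers the
        # female centre f iff x in [f-hi, f-lo]
        lo, hi = self.mgrid.lo, self.mgrid.hi
        W, H = self.fnear.shape
        self.fnear[
            max(fx - hi, 0) : min(fx - lo, W - 1) + 1,
            max(fy - hi, 0) : min(fy - lo, H - 1) + 1,
        ] += delta

    # ----------------------------------------------------------- daily cycle
    def daily_step(self) -> None:
        self.day_of_year += 1
        if self.day_of_year > YEAR_DAYS:
            self.day_of_year = 1
            self.year += 1
        doy = self.day_of_year
        season = in_breeding_season(doy, self.cfg.season)
        v = self.voles
        n = v.n
        rng = self.rng
        p = self.cfg.vole_params

        if n and v.alive[:n].any():
            self._vole_step(doy, season)

        # predators hunt (2) and disperse (3); exposure uses each vole's
        # daily foraging position — a small excursion around the territory —
        # so territory gaps between predator squares are not absolute refuges
        alive_idx = np.flatnonzero(v.alive[: v.n])
        killed_any = np.zeros(alive_idx.size, dtype=bool)
        vx, vy = v.x[alive_idx], v.y[alive_idx]
        fr = p.forage_radius_m // self.cfg.cell_size_m
        if fr > 0 and alive_idx.size:
            W, H = self.land.width_cells, self.land.height_cells
            vx = np.clip(vx + rng.integers(-fr, fr + 1, alive_idx.size), 0, W - 1)
            vy = np.clip(vy + rng.integers(-fr, fr + 1, alive_idx.size), 0, H - 1)
        for g in self.groups:
            killed, exposed = g.hunt_step(vx, vy, rng)
            killed_any |= killed
            acc = self._diag_acc[g.ptype.value]
            acc["exposure_days"] += exposed
            acc["predator_days"] += g.n_alive
            g.dispersal_step(rng)

        # mortality (4): predation, starvation, lifespan
        if alive_idx.size:
            starv = v.dmat[alive_idx] > p.starvation_days
            old = v.age[alive_idx] >= p.lifespan_days
            dead = killed_any | starv | old
            if dead.any():
                didx = alive_idx[dead]
                self.audit["deaths_predation"] += int(killed_any[dead].sum())
                self.audit["deaths_starvation"] += int(
                    (starv & ~killed_any)[dead].sum()
                )
                self.audit["deaths_lifespan"] += int(
                    (old & ~killed_any & ~starv)[dead].sum()
                )
                v.alive[didx] = False
                for i in didx[v.has_terr[didx]]:
                    self._release_territory(int(i))
            v.age[alive_idx] += 1

        if self.collect_daily:
            n2 = v.n
            live = v.alive[:n2]
            adult = v.age[:n2] >= p.maturation_age
            self.daily_rows.append(
                {
                    "year": self.year, "day_of_year": doy,
                    "adult_f": int((live & adult & (v.sex[:n2] == F)).sum()),
                    "adult_m": int((live & adult & (v.sex[:n2] == M)).sum()),
                    "juveniles": int((live & ~adult).sum()),
                    "births_cum": self.audit["births"],
                    "deaths_predation_cum": self.audit["deaths_predation"],
                    "deaths_starvation_cum": self.audit["deaths_starvation"],
                    "deaths_lifespan_cum": self.audit["deaths_lifespan"],
                }
            )

        # annual events
        if doy == self.cfg.census_day:
            self._census()
        if doy == YEAR_DAYS:
            self._year_end()
        if doy == APR_1:
            for g in self.groups:
                g.spring_step(rng)
                g.seed_initial(self.cfg.predator_spring_immigrants, rng, n_tries=50)
        # compact the vole arrays when mostly dead
        if v.n > 2048 and v.alive[: v.n].sum() < v.n // 2:
            self._compact_voles()

    # -- vole behaviours (1) ----------------------------------------------
    def _vole_step(self, doy: int, season: bool) -> None:
        v = self.voles
        rng = self.rng
        p = self.cfg.vole_params
        n = v.n
        alive = v.alive[:n]

        # litters age; weaning at day 14
        nursing = alive & (v.lit_age[:n] >= 0)
        if nursing.any():
            v.lit_age[:n][nursing] += 1
            wean = nursing & (v.lit_age[:n] == p.weaning_age)
            widx = np.flatnonzero(wean)
            if widx.size:
                sizes = v.lit_size[widx].astype(np.int64)
                tot = int(sizes.sum())
                xs = np.repeat(v.tx[widx], sizes)
                ys = np.repeat(v.ty[widx], sizes)
                sexes = rng.integers(0, 2, tot).astype(np.int8)
                heads = rng.integers(0, 8, tot).astype(np.int8)
                v.add(xs, ys, sexes, np.full(tot, p.weaning_age), heads)
                self.audit["births"] += tot
                n = v.n
                alive = v.alive[:n]
                v.lit_age[widx] = -1
                v.lit_size[widx] = 0

        # gestation and birth
        preg = alive & (v.preg[:n] >= 0)
        if preg.any():
            v.preg[:n][preg] -= 1
            born = preg & (v.preg[:n] < 0)
            bidx = np.flatnonzero(born)
            if bidx.size:
                v.preg[bidx] = -1
                v.lit_age[bidx] = 0
                v.lit_size[bidx] = rng.integers(
                    p.litter_min, p.litter_max + 1, bidx.size
                )

        # mating: a territorial mature female mates when a male territory
        # overlaps her position (the nearest such male; identity has no
        # further dynamical consequence, so only coverage is tested here)
        if season:
            elig = (
                alive
                & (v.sex[:n] == F)
                & (v.age[:n] >= p.maturation_age)
                & v.has_terr[:n]
                & (v.preg[:n] < 0)
                & (v.lit_age[:n] < 0)
            )
            eidx = np.flatnonzero(elig)
            if eidx.size:
                covered = self.mgrid.cover[v.tx[eidx], v.ty[eidx]] > 0
                v.preg[eidx[covered]] = p.gestation_days

        # territory assessment / acquisition for itinerant voles, then
        # dispersal movement for those that fail
        seek = alive & ~v.has_terr[:n]
        sidx = np.flatnonzero(seek)
        if sidx.size:
            sidx = sidx[rng.permutation(sidx.size)]  # daily shuffled schedule
            near = self.near_habitat[v.x[sidx], v.y[sidx]]
            cand_idx = sidx[near]
            females = cand_idx[v.sex[cand_idx] == F]
            males = cand_idx[v.sex[cand_idx] == M]
            settled = np.zeros(n, dtype=bool)
            if females.size:
                valid = self.fgrid.valid_mask(self.optimal)
                cx, cy, found = self.search.query(valid, v.x[females], v.y[females])
                hit = np.flatnonzero(found)
                for k in hit:
                    i, fx, fy = int(females[k]), int(cx[k]), int(cy[k])
                    # revalidate: an earlier claim this day may block the site
                    if self.optimal[fx, fy] and self.fgrid.can_place(fx, fy):
                        self._grant_territory(i, fx, fy, F)
                        settled[i] = True
            if males.size:
                valid = self.mgrid.valid_mask(self.optimal)
                prefer = (self.fnear > 0) if season else None
                cx, cy, found = self.search.query(
                    valid, v.x[males], v.y[males], prefer=prefer
                )
                hit = np.flatnonzero(found)
                for k in hit:
                    i, mx, my = int(males[k]), int(cx[k]), int(cy[k])
                    if self.optimal[mx, my] and self.mgrid.can_place(mx, my):
                        self._grant_territory(i, mx, my, M)
                        settled[i] = True
            # failed seekers drift (directed walk with jitter) and risk starvation
            drift = sidx[~settled[sidx]]
            if drift.size:
                self._move_itinerants(drift)
            # infanticide by itinerant mature males encountering nursing females
            im = drift[(v.sex[drift] == M) & (v.age[drift] >= p.maturation_age)]
            if im.size:
                owners = self.fgrid.owner[v.x[im], v.y[im]]
                mothers = owners[owners >= 0]
                if mothers.size:
                    litage = v.lit_age[mothers]
                    active = (litage >= 0) & (litage < p.weaning_age)
                    mothers = mothers[active]
                    if mothers.size:
                        probs = p.infanticide_p0 * (
                            1.0 - v.lit_age[mothers] / p.weaning_age
                        )
                        hit = rng.random(mothers.size) < probs
                        v.lit_age[mothers[hit]] = -1
                        v.lit_size[mothers[hit]] = 0

    def _move_itinerants(self, idx: np.ndarray) -> None:
        v = self.voles
        rng = self.rng
        W, H = self.land.width_cells, self.land.height_cells
        step = DIRS8[v.heading[idx]] * self.move_cells
        jit = rng.integers(-1, 2, (idx.size, 2))
        nx = v.x[idx] + step[:, 0] + jit[:, 0]
        ny = v.y[idx] + step[:, 1] + jit[:, 1]
        hit = (nx < 0) | (nx >= W) | (ny < 0) | (ny >= H)
        nx = np.clip(nx, 0, W - 1)
        ny = np.clip(ny, 0, H - 1)
        v.x[idx], v.y[idx] = nx, ny
        # bounce to a fresh heading at the walls, occasional small turns elsewhere
        if hit.any():
            v.heading[idx[hit]] = rng.integers(0, 8, int(hit.sum()))
        turn = rng.random(idx.size) < 0.1
        v.heading[idx[turn]] = (
            v.heading[idx[turn]] + rng.choice((-1, 1), int(turn.sum()))
        ) % 8
        on_matrix = ~self.optimal[nx, ny]
        v.dmat[idx] = np.where(on_matrix, v.dmat[idx] + 1, 0).astype(np.int16)

    # -------------------------------------------------------- annual events
    def _census(self) -> None:
        v = self.voles
        count = int(v.alive[: v.n].sum())
        opt_ha = self.land.habitat_area_m2 / 1e4
        tot_ha = self.land.width_m * self.land.height_m / 1e4
        alive_idx = np.flatnonzero(v.alive[: v.n])
        pos = np.column_stack((v.x[alive_idx], v.y[alive_idx]))
        self._occupancy_at_census = patch_occupancy(self.land, pos)
        self._census_row = {
            "year": self.year,
            "count": count,
            "density_opt_ha": count / opt_ha,
            "density_total_ha": count / tot_ha,
            "patch_occupancy": self._occupancy_at_census,
        }

    def _year_end(self) -> None:
        row = dict(getattr(self, "_census_row", {"year": self.year, "count": 0}))
        for g in self.groups:
            d = g.year_end()
            acc = self._diag_acc[g.ptype.value]
            t = g.ptype.value.lower()
            row[f"{t}_n"] = d["n_predators"]
            row[f"{t}_zero_kill_days"] = d["mean_zero_kill_days"]
            row[f"{t}_kills"] = d["total_kills"]
            row[f"{t}_exposure_days"] = acc["exposure_days"]
            row[f"{t}_predator_days"] = acc["predator_days"]
            row[f"{t}_kills_per_predator_day"] = (
                d["total_kills"] / acc["predator_days"] if acc["predator_days"] else float("nan")
            )
            row[f"{t}_kills_per_vole_day"] = (
                d["total_kills"] / acc["exposure_days"] if acc["exposure_days"] else float("nan")
            )
            acc["exposure_days"] = 0
            acc["predator_days"] = 0
        self._year_rows.append(row)

    def _compact_voles(self) -> None:
        v = self.voles
        v.compact()
        # rebuild territory owner rasters with the new indices
        self.fgrid.owner[self.fgrid.owner >= 0] = -1
        self.mgrid.owner[self.mgrid.owner >= 0] = -1
        terr = np.flatnonzero(v.has_terr[: v.n])
        fem = terr[v.sex[terr] == F]
        mal = terr[v.sex[terr] == M]
        self.fgrid.owner[v.tx[fem], v.ty[fem]] = fem
        self.mgrid.owner[v.tx[mal], v.ty[mal]] = mal

    # ---------------------------------------------------------- diagnostics
    @property
    def vole_count(self) -> int:
        return int(self.voles.alive[: self.voles.n].sum())

    def diagnostics(self) -> dict:
        """Year-to-date predator diagnostics plus current patch occupancy.

        ``failure_day_fraction`` is the mean over living predators of days
        without a successful kill divided by the days elapsed this year;
        missing (NaN) when no predators are alive.  Predation rate is
        reported both as kills per vole-exposure-day and kills per
        predator-day.
        """
        v = self.voles
        alive_idx = np.flatnonzero(v.alive[: v.n])
        pos = np.column_stack((v.x[alive_idx], v.y[alive_idx]))
        out = {"patch_occupancy": patch_occupancy(self.land, pos)}
        days = self.day_of_year if self.day_of_year else YEAR_DAYS
        for g in self.groups:
            t = g.ptype.value.lower()
            acc = self._diag_acc[g.ptype.value]
            if g.n_alive:
                out[f"{t}_failure_day_fraction"] = float(
                    g.zero_kill_days[g.alive].mean() / days
                )
            else:
                out[f"{t}_failure_day_fraction"] = float("nan")
            kills = int(g.kills[g.alive].sum()) if g.n_alive else 0
            out[f"{t}_kills_per_vole_day"] = (
                kills / acc["exposure_days"] if acc["exposure_days"] else float("nan")
            )
            out[f"{t}_kills_per_predator_day"] = (
                kills / acc["predator_days"] if acc["predator_days"] else float("nan")
            )
        return out


def replicate_rng(config: ScenarioConfig, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.master_seed,
        spawn_key=(config.scenario_index, replicate),
    )
    return np.random.default_rng(ss)


def run_replicate(config: ScenarioConfig, replicate: int) -> RunResult:
    """Run one replicate: burn-in plus sampled years with an annual census."""
    world = World(config, replicate_rng(config, replicate))
    total_years = config.burn_in_years + config.sample_years
    for _ in range(total_years * YEAR_DAYS):
        world.daily_step()
    diag = pd.DataFrame(world._year_rows)
    sampled = diag[diag["year"] >= config.burn_in_years].reset_index(drop=True)
    counts = sampled["count"].to_numpy()
    opt_ha = world.land.habitat_area_m2 / 1e4
    tot_ha = config.width_m * config.height_m / 1e4
    series = VoleTimeSeries(
        scenario_id=config.scenario_id,
        replicate=replicate,
        counts=counts,
        density_opt_ha=counts / opt_ha,
        density_total_ha=counts / tot_ha,
        census_day=config.census_day,
        extinct=bool((counts == 0).any()),
    )
    return RunResult(series=series, diagnostics=sampled)


def run_scenario(config: ScenarioConfig) -> list[RunResult]:
    """All replicates of one scenario (serial, deterministic per seed)."""
    return [run_replicate(config, r) for r in range(config.replicates)]


# ------------------------------------------------------------------ file IO
def write_run(outdir, config: ScenarioConfig, results: list[RunResult]) -> None:
    """One CSV per replicate (year, count, densities) plus a JSON manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for res in results:
        s = res.series
        df = pd.DataFrame(
            {
                "year": np.arange(len(s.counts)),
                "count": s.counts,
                "density_opt_ha": s.density_opt_ha,
                "density_total_ha": s.density_total_ha,
            }
        )
        df.to_csv(out / f"{s.scenario_id}_rep{s.replicate}.csv", index=False)
        res.diagnostics.to_csv(
            out / f"{s.scenario_id}_rep{s.replicate}_diag.csv", index=False
        )
    manifest = {
        "scenario_id": config.scenario_id,
        "config": {
            k: getattr(config, k)
            for k in (
                "predator_assembly", "n_patches", "breeding_season", "width_m",
                "height_m", "habitat_fraction", "cell_size_m", "burn_in_years",
                "sample_years", "replicates", "master_seed", "census_day",
            )
        },
    }
    (out / f"{config.scenario_id}_manifest.json").write_text(json.dumps(manifest, indent=2))
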