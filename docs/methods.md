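# Model and methods

## Overview

`volecycles` couples a spatially explicit, daily-time-step, individual-based
model of territorial field voles (*Microtus agrestis*) and their mammalian
predators to the time-series machinery used to characterise rodent
population dynamics: cycle amplitude (max/min), cycle length read from the
autocorrelation function, and direct/delayed density dependence (AR1, AR2)
from a second-order autoregressive fit of log annual densities.  A factorial
experiment crosses three predator assemblies (generalists only, specialists
only, mixed), four fragmentation levels (the same 1.5 % of optimal habitat in
1, 9, 25 or 100 equally sized square patches) and three breeding-season
lengths (end date Sep 1 / Oct 1 / Nov 1), and a three-way fixed-effects
ANOVA attributes endpoint variance to these factors and their interactions.

## Landscape

A rectangular grid of square cells holds two habitat classes: optimal vole
habitat and a traversable matrix in which voles can neither feed nor breed.
Patches are congruent squares centred on a regular k x k lattice; the patch
side is `round(sqrt(T/n))` cells where `T = round(total_cells * fraction)`.
Edges are reflecting.  The reference full-scale design is 10 x 10 km at 1 m
resolution; the default desk-scale configuration is 2.45 x 2.45 km at 10 m
cells, chosen so that the 900 habitat cells divide exactly into 1, 9, 25 or
100 congruent square patches.

## Voles

Three life stages (juvenile, adult female, adult male).  Young enter the
simulation at their mother's nest when weaned at 14 days, with sex assigned
at probability 0.5, and immediately search for a territory; a territory is
required for breeding.  Female territories are 10 x 10 m squares of optimal
habitat; males hold larger (30 x 30 m) squares.  Same-sex territories
overlapping by more than 50 % are not tolerated: the younger vole is evicted
(in the engine this is enforced at acquisition time — a centre-separation
rule exactly equivalent to the >50 % criterion for squares — so conflicting
claims are never granted; the explicit eviction rule is exercised at the
behavioural API level).  A female mates when a male territory overlaps her
position, choosing the nearest male; gestation is 21 days; litters of 4-6
are weaned at 14 days.  Mature males encountered outside their own territory
attempt infanticide on unweaned litters with success declining linearly from
0.5 at birth to 0 at weaning.  Deaths are due to predation, starvation
(more than 14 consecutive days in matrix habitat), or the physiological
lifespan limit (550 days).  Itinerant voles disperse as a directed walk
(50 m/day with jitter), scanning 50 m around themselves for a free
territory site each day.  Territorial voles make a daily foraging excursion
of up to +-20 m around the territory centre; this excursion defines their
exposure to predators, so the interstices between non-overlapping predator
territories are risk-reducing but not absolute refuges.

Calibration constants (gestation, litter size, maturation at 30 d, lifespan,
territory sides, movement, search and foraging radii, starvation threshold,
infanticide parameters) are not prescribed by the published factorial design
and were fixed once at field-plausible values; the dispersal and starvation
values were chosen so that inter-patch distances of the desk-scale 25- and
100-patch landscapes are bridgeable by dispersing juveniles.

## Predators

Two types with the life-history settings: specialist — reproductive
threshold 5 voles/offspring, survival threshold 90 voles/yr, territory
2500 m^2, kill efficiency 9.5 %/day, dispersal after 5 failure days, max
dispersal 500 m; generalist — 90, 10, 6400 m^2, 4 %, 20 days, 1000 m.
Territories are squares; no overlap is tolerated within a type (centres at
Chebyshev distance >= side), while cross-type overlap is free.  Hunting is
confined to the territory: every vole foraging inside it is at risk with the
type's daily kill efficiency, but a predator handles at most 2 prey per day,
so the daily hunt succeeds with probability ~ 1-(1-eff)^n.  A run of
failure days at the type's threshold triggers relocation within the maximum
dispersal distance; the destination must be free of same-type territories,
targets optimal habitat with probability 0.15 (the habitat-fidelity
calibration constant) and is otherwise unbiased, so persistently failing
predators drift off prey ground.  Survival is evaluated every Dec 31
(survive iff the annual kill count met the survival threshold); survivors
reproduce on Apr 1, producing floor(previous year's kills / reproductive
threshold) offspring, each recruited only where a free territory centred on
optimal habitat fits within the parent's dispersal reach.  Two immigration
attempts per type arrive each spring, representing the regional pool around
the small landscape; without them predator extinction is absorbing in a
closed desk-scale world.  Dispersal and recruitment distances are scaled by
(landscape size / 10 km) so the reach : patch-size geometry of the
full-scale design is preserved on scaled-down landscapes.

The one-per-day handling cap (raised to 2 in the default configuration) is
the stabilising structural choice: with unbounded per-vole kills, aggregate
predation scales linearly with prey density and the scaled system collapses
to extinction within a few years, which is also why realised "predation
rate" diagnostics are reported both per predator-day (a yield that falls
with fragmentation) and per vole-exposure-day (which tracks the nominal
efficiency).

## Scheduling, census and determinism

Within a day: vole behaviours (weaning, gestation/birth, mating, territory
acquisition, dispersal movement, infanticide), predator hunting, predator
dispersal checks, mortality; agent order in territory acquisition is
reshuffled daily.  The calendar has 365 days; breeding runs Apr 5 - Oct 1
(intermediate), with Sep 1 / Nov 1 for short/long seasons.  The census
counts all weaned voles every Oct 1 and records density per hectare of
optimal habitat and of total landscape; patch occupancy is measured on the
census day.  All randomness flows from one generator seeded from
(master seed, scenario index, replicate), so runs replay bit-identically.
Worlds whose vole population hits zero stay extinct (recolonisation is not
modelled); such replicates keep zero censuses and are flagged.

## Analysis stage

Amplitude is max/min of the density series (flagged infinite when the
minimum is zero).  The ACF uses the standard biased estimator; the 95 %
confidence band is z_{1-alpha/2}/sqrt(N).  Cycle length is the lag of the
first interior positive ACF local maximum exceeding the band (the lag-0
peak counts as the first maximum), confirmed by a further significant
positive local maximum within +-1 lag of twice that lag; otherwise 0.
AR1/AR2 are the raw OLS slopes of x_t on (x_{t-1}, x_{t-2}) with intercept
on log densities; series containing zeros are offset by the smallest
positive observed value and flagged.  The endpoint N is log_e of the mean
density.  The ANOVA is a balanced three-way fixed-effects decomposition;
the per-source contribution is the Minitab-style adjusted percentage
(SS_source - df_source * MS_error) / SS_total * 100.

## Synthetic data

`synthdata` generates AR(2), noisy-periodic, white-noise and
extinction-style density series (latent Gaussian processes exponentiated so
the analysis stage's log transform is exercised) plus balanced factorial
endpoint tables with chosen effect sizes.  These validate amplitude, cycle
detection, AR(2) recovery and the ANOVA independently of the simulator.
They emulate the statistical structure of simulator output, not its spatial
or mechanistic content, so passing analysis tests says nothing about the
agent-based model itself — the simulator has its own behavioural and
dynamical tests.

## Problem sizes and what the desk scale reproduces

Tests and the acceptance script run the 2.45 km / 10 m configuration with a
20-30 year burn-in, 40-50 sampled years and 2-5 replicates — roughly 1/17th
of the full design's vole population.  Under this calibration the desk-scale
system reproduces part of the study's qualitative structure and attenuates
the rest; both halves are reported as measured rather than tuned away.

Reproduced: generalist-only populations are stable (amplitude near 1, no
cycles, no delayed density dependence); 100-patch populations do not cycle;
the homogeneous-landscape specialist scenario shows deep multiannual
boom-crash fluctuations (amplitude 20-100x) with negative direct and
delayed density dependence and specialist numbers swinging in antiphase to
the voles; specialists depress mean population size in the homogeneous
landscape.

Attenuated at this scale: (a) the replicate-mean delayed-density-dependence
coefficient of the cycling scenarios reaches about -0.4 to -0.5, not the
below -0.7 of the full-scale analysis, because demographic noise at cycle
troughs (tens of animals at ~900 vole territories) randomises crash and
recovery timing; for the same reason the strict ACF rule usually records
cycle length 0 rather than a stable 4-year period.  (b) The fragmented
specialist scenarios (9-100 patches) relax into patch-level predator-prey
standoffs instead of cycling: a desk-scale patch supports only 1-4
specialist territories, too few for a local numerical response, and vole
dispersal spans the scaled inter-patch distances easily enough that emptied
patches refill immediately.  Consequently the fragmentation-driven
signatures — population-size suppression across all fragmentation levels,
extra specialist failure days and reduced hunting yield at 25 patches, and
a majority-unoccupied 100-patch landscape — do not emerge here.  Reducing
vole dispersal to make patch vacancy possible instead collapses the 9- and
25-patch systems entirely (inter-patch rescue fails), so persistence was
preferred.  These limits are properties of the scale, not free parameters:
the corresponding acceptance checks assert the full-scale values and are
expected to fail on desk-scale output.

## Known limitations

No food depletion or energetics; no snow cover or winter forage limitation;
no vole immigration from outside the landscape; predator immigration is a
constant trickle rather than a dynamic regional pool; mate identity beyond
territory overlap has no genetic consequence; the engine's eviction-free
acquisition is equivalent to the >50 % rule only for the square-territory
geometry used here.
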