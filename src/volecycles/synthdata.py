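"""Synthetic annual density series and factorial endpoint fixtures.

These generators produce series with the statistical structure the analysis
stage assumes — AR(2) log-densities, noisy periodic cycles, white noise, and
extinction-style series with zeros — so that amplitude, cycle detection and
the autoregressive fits can be validated without running the simulator.
Latent processes are exponentiated to positive densities so the analysis
stage's log transform is exercised.  All generators are deterministic per
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic series.

    kind: "AR2", "PERIODIC", "WHITE" or "EXTINCTION".  For AR2 the
    coefficients must lie inside the stationarity triangle
    (|ar2| < 1, ar2 + ar1 < 1, ar2 - ar1 < 1).
    """

    kind: str = "AR2"
    n: int = 100
    ar1: float = 0.0
    ar2: float = 0.0
    period: float = 4.0
    snr: float = 4.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"AR2", "PERIODIC", "WHITE", "EXTINCTION"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "AR2" and not (
            abs(self.ar2) < 1 and self.ar2 + self.ar1 < 1 and self.ar2 - self.ar1 < 1
        ):
            raise ValueError("AR2 coefficients outside the stationarity triangle")


def ar2_quasi_period(ar1: float, ar2: float) -> float:
    """Quasi-period 2*pi/arccos(ar1 / (2*sqrt(-ar2))) of a complex-root AR(2)."""
    if ar2 >= 0 or ar1 * ar1 + 4 * ar2 >= 0:
        raise ValueError("AR(2) roots are real; no quasi-period")
    return 2 * math.pi / math.acos(ar1 / (2 * math.sqrt(-ar2)))


def gen_ar2(spec: SyntheticSpec, burn: int = 200) -> np.ndarray:
    """Positive density series whose log follows x_t = ar1 x_{t-1} + ar2 x_{t-2} + eps."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n + burn
    e = rng.normal(0.0, spec.sigma, n)
    x = np.zeros(n)
    for t in range(2, n):
        x[t] = spec.ar1 * x[t - 1] + spec.ar2 * x[t - 2] + e[t]
    return np.exp(x[burn:])


def gen_periodic(spec: SyntheticSpec) -> np.ndarray:
    """Exponentiated sinusoid of the given period plus noise at the given SNR.

    SNR is the signal-to-noise variance ratio (A^2/2) / sigma_noise^2 with
    unit sine amplitude; snr = inf gives the noiseless exp(sin) series, whose
    amplitude (max/min) is e^2 when the sampling grid hits the sine extremes
    (true for integer periods dividing 4... more precisely whenever period
    divides 4k; for period 4 the samples are 0, 1, 0, -1, ...).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n)
    signal = np.sin(2 * math.pi * t / spec.period)
    if math.isinf(spec.snr):
        noise = 0.0
    else:
        if spec.snr <= 0:
            raise ValueError("snr must be positive (use inf for noiseless)")
        noise = rng.normal(0.0, math.sqrt(0.5 / spec.snr), spec.n)
    return np.exp(signal + noise)


def gen_white(spec: SyntheticSpec) -> np.ndarray:
    """Exponentiated Gaussian white noise (log-series is iid normal)."""
    rng = np.random.default_rng(spec.seed)
    return np.exp(rng.normal(0.0, spec.sigma, spec.n))


def gen_extinction(spec: SyntheticSpec, extinct_from: float = 0.7) -> np.ndarray:
    """White-noise-like series that collapses to zeros for the final stretch."""
    x = gen_white(spec)
    x[int(spec.n * extinct_from):] = 0.0
    return x


def generate(spec: SyntheticSpec) -> np.ndarray:
    return {
        "AR2": gen_ar2,
        "PERIODIC": gen_periodic,
        "WHITE": gen_white,
        "EXTINCTION": gen_extinction,
    }[spec.kind](spec)


def gen_grid_fixture(
    effects: dict | None = None,
    replicates: int = 20,
    sigma: float = 1.0,
    seed: int = 0,
    levels: tuple = ((1, 9, 25, 100), ("GENERALIST_ONLY", "SPECIALIST_ONLY", "MIXED"),
                     ("SHORT", "INTERMEDIATE", "LONG")),
) -> pd.DataFrame:
    """Balanced factorial endpoint table with chosen main/interaction effects.

    ``effects`` maps source names ("L", "Pr", "B", "L*Pr", ...) to effect
    scales; each source contributes ``scale * z_level`` where z_level is a
    fixed standard-normal draw per factor-level combination.  Gaussian noise
    with sd ``sigma`` is added per row.  The result has columns L, Pr, B,
    replicate, response.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    Ls, Prs, Bs = levels
    rows = []
    level_effects: dict[tuple, float] = {}

    def eff(source: str, key: tuple) -> float:
        scale = effects.get(source, 0.0)
        if scale == 0.0:
            return 0.0
        if (source, key) not in level_effects:
            level_effects[(source, key)] = rng.standard_normal()
        return scale * level_effects[(source, key)]

    for L in Ls:
        for Pr in Prs:
            for B in Bs:
                base = (
                    eff("L", (L,)) + eff("Pr", (Pr,)) + eff("B", (B,))
                    + eff("L*Pr", (L, Pr)) + eff("L*B", (L, B)) + eff("Pr*B", (Pr, B))
                    + eff("L*Pr*B", (L, Pr, B))
                )
                for r in range(replicates):
                    rows.append(
                        {"L": L, "Pr": Pr, "B": B, "replicate": r,
                         "response": base + rng.normal(0.0, sigma)}
                    )
    return pd.DataFrame(rows)
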