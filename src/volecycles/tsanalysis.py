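"""Endpoint extraction from annual vole density series.

For each sampled series the pipeline records the log mean population size,
the cycle amplitude (max/min), the cycle length read from the
autocorrelation function, and the coefficients of direct (AR1) and delayed
(AR2) density dependence from a second-order autoregressive fit of the
log-transformed densities:

    x_t = c + phi_1 x_{t-1} + phi_2 x_{t-2} + eps_t

Strongly negative phi_2 (delayed density dependence) is the classical
signature of specialist predator-prey coupling and produces multiannual
cycles; phi_1 measures direct (within-year) regulation.

Cycle length is the lag L at which the ACF reaches its second positive
significant (p < alpha) maximum, counting the lag-0 peak as the first; a
further positive significant local maximum within +/-1 lag of 2L is required
as evidence of stable fluctuations, otherwise the series is recorded as
non-cyclic (length 0).  Significance uses the white-noise band
z_{1-alpha/2} / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf


@dataclass
class CycleResult:
    """Cycle diagnostics for one series: 0 cycle length means no stable periodicity."""

    cycle_length_years: int
    amplitude: float  # max/min; inf flags an extinction replicate
    acf_values: np.ndarray
    ci_halfwidth: float


@dataclass
class DensityDependence:
    """AR(2) regression summary: ar1 = direct, ar2 = delayed density dependence."""

    ar1: float
    ar2: float
    intercept: float
    resid_var: float
    n_obs: int


def log_density(series, zero_offset: float | None = None) -> np.ndarray:
    """Natural log of a density series.

    Zeros are rejected unless ``zero_offset`` is given, in which case the
    offset (conventionally the smallest positive observed value, for
    replicates with extinctions) is added to every observation first.
    """
    x = np.asarray(series, dtype=float)
    if zero_offset is not None:
        x = x + zero_offset
    if (x <= 0).any():
        raise ValueError("log_density requires positive values (set zero_offset)")
    return np.log(x)


def amplitude(series) -> float:
    """Cycle amplitude = max / min of the series; inf if the minimum is 0."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if (x < 0).any():
        raise ValueError("densities must be non-negative")
    lo = x.min()
    if lo == 0:
        return math.inf
    return float(x.max() / lo)


def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelation (biased estimator, normalised by lag 0)."""
    x = np.asarray(series, dtype=float)
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    return _sm_acf(x, nlags=max_lag, fft=False, adjusted=False)


def ci_halfwidth(n: int, alpha: float = 0.05) -> float:
    """Half-width z_{1-alpha/2}/sqrt(N) of the white-noise ACF confidence band."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(stats.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n))


def default_max_lag(n: int) -> int:
    return min(n // 4, 25)


def _local_maxima(r: np.ndarray) -> list[int]:
    """Interior local maxima (strictly greater than both neighbours; plateaus
    resolve toward the smaller lag)."""
    out = []
    for k in range(1, r.size - 1):
        if r[k] > r[k + 1] and r[k] > r[k - 1]:
            out.append(k)
        elif r[k] == r[k - 1]:
            continue  # plateau: the earlier lag already claimed it (or will not)
        elif r[k] > r[k - 1] and r[k] == r[k + 1]:
            # start of a plateau that eventually falls: treat as the maximum
            j = k + 1
            while j < r.size - 1 and r[j] == r[k]:
                j += 1
            if j < r.size and r[j] < r[k]:
                out.append(k)
    return out


def cycle_length(series, alpha: float = 0.05, max_lag: int | None = None) -> CycleResult:
    """Cycle period (years) from the ACF second-positive-significant-maximum rule.

    The lag-0 peak counts as the first positive significant maximum.  The
    candidate period L is the first interior local ACF maximum that is
    positive and exceeds the white-noise band; stability requires another
    positive significant local maximum within +/-1 lag of 2L.  Returns a
    :class:`CycleResult` with cycle length 0 when no stable periodicity is
    found.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("cycle_length requires a series of length >= 20")
    if max_lag is None:
        max_lag = default_max_lag(x.size)
    r = acf(x, max_lag)
    ci = ci_halfwidth(x.size, alpha)
    amp = amplitude(x)
    maxima = [k for k in _local_maxima(r) if r[k] > ci]
    length = 0
    if maxima:
        L = maxima[0]
        if any(abs(m - 2 * L) <= 1 for m in maxima if m > L):
            length = L
    return CycleResult(
        cycle_length_years=length, amplitude=amp, acf_values=r, ci_halfwidth=ci
    )


def fit_ar2(log_series) -> DensityDependence:
    """OLS fit of x_t on (x_{t-1}, x_{t-2}) with intercept.

    ``ar1`` and ``ar2`` are the raw regression slopes phi_1 and phi_2.  The
    alternative (1 + a_1) convention used in parts of the rodent literature is
    ``ar1 - 1`` on this scale; callers wanting it can subtract 1.
    """
    x = np.asarray(log_series, dtype=float)
    if x.size < 10:
        raise ValueError("fit_ar2 requires a series of length >= 10")
    if np.ptp(x) == 0:
        raise ValueError("fit_ar2 requires a series with positive variance")
    y = x[2:]
    X = np.column_stack([np.ones(y.size), x[1:-1], x[:-2]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - 3, 1)
    return DensityDependence(
        ar1=float(beta[1]),
        ar2=float(beta[2]),
        intercept=float(beta[0]),
        resid_var=float(resid @ resid / dof),
        n_obs=int(y.size),
    )


def analyze_series(series, alpha: float = 0.05) -> dict:
    """All endpoints for one annual density series.

    Returns a dict with ``meanN_log`` (log of the mean density), ``amplitude``,
    ``cycle_length``, ``ar1``, ``ar2`` and an ``extinct`` flag.  Series
    containing zeros are offset by the smallest positive observed value
    before the log transform and flagged; all-zero series yield NaN endpoints
    with cycle length 0.
    """
    x = np.asarray(series, dtype=float)
    extinct = bool((x == 0).any())
    if (x > 0).any():
        offset = float(x[x > 0].min()) if extinct else None
        lx = log_density(x, zero_offset=offset)
        cyc = cycle_length(x, alpha=alpha)
        dd = fit_ar2(lx) if np.ptp(lx) > 0 else None
        return {
            "meanN_log": float(np.log(x.mean())),
            "amplitude": cyc.amplitude,
            "cycle_length": cyc.cycle_length_years,
            "ar1": dd.ar1 if dd else float("nan"),
            "ar2": dd.ar2 if dd else float("nan"),
            "extinct": extinct,
        }
    return {
        "meanN_log": float("nan"),
        "amplitude": float("inf"),
        "cycle_length": 0,
        "ar1": float("nan"),
        "ar2": float("nan"),
        "extinct": True,
    }
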