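"""Time-domain population coupling and refractory-contamination QC.

The coupling curve is the lagged inner product between the population rate
and a single unit's (optionally smoothed) spike train, normalised by the
unit's spike count, with a far-lag baseline subtracted — the time-domain
counterpart of the coherence analysis, at 1 ms (fast) or 1 s (slow)
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .core import (
    ContinuousSignal,
    EmptyInputError,
    InsufficientDataError,
    InvalidArgumentError,
    SpikeTrain,
)

__all__ = ["CouplingCurve", "coupling_xcorr", "refractory_contamination"]

_TIMESCALES = {
    # dt, max lag, smoothing HWHM of the unit train, baseline lag window
    "fast": dict(dt=1e-3, max_lag=1.0, hwhm=12e-3, baseline=(0.8, 1.0)),
    "slow": dict(dt=1.0, max_lag=20.0, hwhm=None, baseline=(12.0, 20.0)),
}


@dataclass
class CouplingCurve:
    """Baseline-subtracted population-rate co-modulation per unit spike."""

    lags: np.ndarray
    value: np.ndarray
    timescale: str
    baseline: float = 0.0
    meta: dict = field(default_factory=dict)


def coupling_xcorr(
    spikes: SpikeTrain, pop_rate: ContinuousSignal, timescale: str = "slow"
) -> CouplingCurve:
    """Cross-correlation of a unit with the population rate.

    ``fast``: 1 ms resolution, the unit train smoothed with a Gaussian of
    12 ms half-width at half-maximum, lags to +-1 s, baseline from lags
    0.8-1 s.  ``slow``: 1 s resolution, lags to +-20 s, baseline from lags
    12-20 s.  Values are (population) spikes/s per unit spike; a positive
    lag means the population rate is taken after the unit's spikes.
    """
    if spikes.n_spikes == 0:
        raise EmptyInputError("unit has no spikes")
    if timescale not in _TIMESCALES:
        raise InvalidArgumentError("timescale must be 'fast' or 'slow'")
    p = _TIMESCALES[timescale]
    dt = p["dt"]
    unit = spikes.binned(dt)
    u = unit.values * dt  # back to counts so the product is rate per spike
    if p["hwhm"] is not None:
        sigma = p["hwhm"] / math.sqrt(2 * math.log(2)) / dt
        u = gaussian_filter1d(u, sigma, mode="constant")
    pop = pop_rate if np.isclose(pop_rate.dt, dt) else pop_rate.resampled(dt)
    n = min(u.size, pop.n)
    y = pop.values[:n]
    u = u[:n]
    nlag = int(round(p["max_lag"] / dt))
    # full cross-correlation sum_t u[t] * y[t + lag], via FFT convolution
    cc = fftconvolve(y, u[::-1], mode="full")
    mid = n - 1
    lags = np.arange(-nlag, nlag + 1) * dt
    vals = cc[mid - nlag : mid + nlag + 1] / spikes.n_spikes
    lo, hi = p["baseline"]
    base_sel = (np.abs(lags) >= lo) & (np.abs(lags) <= hi)
    baseline = float(vals[base_sel].mean())
    return CouplingCurve(lags, vals - baseline, timescale, baseline,
                         meta={"dt": dt, "n_spikes": spikes.n_spikes})


def refractory_contamination(
    spikes: SpikeTrain,
    refractory: float = 2e-3,
    asymptote_window: tuple = (0.05, 0.1),
) -> float:
    """Refractory-period contamination of a unit's autocorrelogram.

    The mean autocorrelogram density in (0, 2 ms] divided by the density in
    the 50-100 ms asymptote window.  A perfectly refractory unit scores 0,
    a homogeneous Poisson train ~1; the screening threshold used for unit
    quality is < 0.2.
    """
    if spikes.n_spikes < 100:
        raise InsufficientDataError("need >= 100 spikes")
    t = spikes.times
    max_lag = asymptote_window[1]
    near = 0
    asym = 0
    k = 1
    while True:
        d = t[k:] - t[:-k]
        within = d <= max_lag
        if not within.any():
            break
        near += int(np.count_nonzero(d[within] <= refractory))
        asym += int(np.count_nonzero((d[within] >= asymptote_window[0])))
        k += 1
    near_density = near / refractory
    asym_density = asym / (asymptote_window[1] - asymptote_window[0])
    if asym_density == 0:
        raise InsufficientDataError("empty autocorrelogram asymptote window")
    return near_density / asym_density
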