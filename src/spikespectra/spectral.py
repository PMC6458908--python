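"""Power spectra of spike trains and continuous signals over 0.01-100 Hz.

Spectra are estimated with a frequency-dependent segmentation: a band just
below ``f_hi`` is estimated from segments of length ``l = 10 / f_hi``, using
the Fourier frequencies ``8/l, 9/l, 10/l`` inside the band, averaged over
``floor(duration / l)`` non-overlapping segments and over ``K`` DPSS tapers
per segment.  The band edges step down geometrically (``f_hi -> 0.75 f_hi``)
so bands tile the analysis range without gaps; for a 2 h recording the top
band uses 72 000 segments of 0.1 s and the band around 0.015 Hz uses 12
segments of 560 s.

All spectra are two-sided densities on the positive frequency axis: the
variance of a continuous signal is ``2 * integral(S df)`` and a homogeneous
Poisson train of rate mu has the flat level ``S(f) = mu``.  With that
convention the point-process identity ``Snn(f) ~= mu + S_ll(f)`` holds,
where ``S_ll`` is the spectrum of the underlying rate intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

from .core import (
    ContinuousSignal,
    EmptyInputError,
    ExclusionEmptyError,
    FitFailureError,
    InsufficientDurationError,
    InvalidArgumentError,
    Recording,
    SpikeTrain,
)

__all__ = [
    "TaperParams",
    "Band",
    "SegmentationPlan",
    "SpectrumEstimate",
    "PowerLawFit",
    "make_segmentation_plan",
    "spiketrain_psd",
    "continuous_psd",
    "fit_power_law",
    "population_rate",
    "psd_sum_ratio",
    "powerlaw_power_fraction",
]

#: ratio between the top edges of consecutive bands; bands are [0.75*f_hi, f_hi]
BAND_RATIO = 0.75
#: frequencies per band are j/l for j in 8..10 (l = 10/f_hi)
_J_LO, _J_HI = 8, 10
#: cap on samples per segment; infraslow bands only need the lowest 10 bins
_MAX_SAMPLES = 1024
_BASE_DT = 1e-3


@dataclass(frozen=True)
class TaperParams:
    """Multitaper parameters: time-bandwidth product and taper count."""

    nw: float = 3.0
    k: int = 5


@dataclass(frozen=True)
class Band:
    """One segmentation band: frequencies ``(f_lo, f_hi]`` from segments of
    length ``segment_length`` sampled at ``segment_length / n_samples``."""

    f_lo: float
    f_hi: float
    segment_length: float
    n_segments: int
    n_samples: int

    @property
    def dt(self) -> float:
        return self.segment_length / self.n_samples

    @property
    def freq_indices(self) -> np.ndarray:
        l = self.segment_length
        j0 = int(np.floor(self.f_lo * l * (1 + 1e-9))) + 1
        j1 = int(np.floor(self.f_hi * l * (1 + 1e-9)))
        return np.arange(j0, j1 + 1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.freq_indices / self.segment_length


@dataclass(frozen=True)
class SegmentationPlan:
    """Ordered (high to low frequency) list of segmentation bands."""

    bands: Tuple[Band, ...]
    duration: float
    f_min: float
    f_max: float

    @property
    def frequencies(self) -> np.ndarray:
        """All analysis frequencies, ascending."""
        return np.concatenate([b.frequencies for b in reversed(self.bands)])


@dataclass
class SpectrumEstimate:
    """Segment- and taper-averaged power spectrum with asymptotic CIs.

    ``power`` is a two-sided density: (spikes/s)^2/Hz for point processes
    (flat level mu for homogeneous Poisson), units^2/Hz otherwise.
    """

    frequencies: np.ndarray
    power: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_segments: np.ndarray
    dof: np.ndarray
    mu: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of ``log power = log const - beta * log f``."""

    beta: float
    const: float
    fit_band: Tuple[float, float]
    r_squared: float
    n_points: int


def make_segmentation_plan(
    duration: float, f_min: float = 0.01, f_max: float = 100.0
) -> SegmentationPlan:
    """Build the frequency-dependent segmentation for ``[f_min, f_max]``.

    Iterates ``f_hi = f_max * 0.75**k`` downward; each band uses segments of
    length ``10 / f_hi`` and stops once the band's lower edge reaches
    ``f_min``.  Raises :class:`InsufficientDurationError` if any required
    band would have fewer than two segments.
    """
    if not (0 < f_min < f_max):
        raise InvalidArgumentError("need 0 < f_min < f_max")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    bands = []
    f_hi = float(f_max)
    while True:
        f_lo = BAND_RATIO * f_hi
        seg = 10.0 / f_hi
        n_seg = int(np.floor(duration / seg))
        if n_seg < 2:
            raise InsufficientDurationError(
                f"duration {duration:g} s gives {n_seg} segment(s) of {seg:g} s "
                f"for the {f_lo:g}-{f_hi:g} Hz band; at least 2 are required"
            )
        if seg <= _MAX_SAMPLES * _BASE_DT:
            n_samples = max(int(round(seg / _BASE_DT)), 32)
        else:
            n_samples = _MAX_SAMPLES
        bands.append(Band(f_lo, f_hi, seg, n_seg, n_samples))
        if f_lo <= f_min:
            break
        f_hi = f_lo
    return SegmentationPlan(tuple(bands), duration, f_min, f_max)


@lru_cache(maxsize=64)
def _tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    h = dpss(n_samples, nw, Kmax=k)
    h = np.atleast_2d(h)
    return h / np.sqrt(np.sum(h**2, axis=1, keepdims=True))


@lru_cache(maxsize=64)
def _demean_correction(n_samples: int, nw: float, k: int) -> np.ndarray:
    """Per-taper, per-bin share of white power kept after subtracting the
    segment mean: ``1 - |H_k(j)|^2 / N``.

    Demeaning projects out the constant vector, which removes a
    deterministic fraction of broadband power through each taper's leakage
    (about 1% at the band bins of 100-sample segments — larger than the
    CI width when tens of thousands of segments are averaged).  Dividing
    by this factor makes the estimator unbiased for white input.
    """
    h = _tapers(n_samples, nw, k)
    leak = np.abs(np.fft.rfft(h, axis=1)) ** 2 / n_samples
    return 1.0 - leak


def _band_layout(band: Band, native_dts: Sequence[float]) -> Tuple[int, float]:
    """Segment grid (n_samples, dt) for a band, honouring the coarsest
    continuous input.

    When a continuous signal is sampled as coarsely as (or coarser than)
    the band's default grid, segments are cut on the signal's own grid —
    upsampling piecewise-constant data would attenuate power near the
    signal's Nyquist frequency.  Finer signals are integrate-and-averaged
    onto the band grid, where the analysis frequencies sit far below the
    native Nyquist and the averaging loss is negligible.
    """
    coarsest = max(native_dts, default=0.0)
    if coarsest > 0 and band.segment_length / coarsest <= band.n_samples + 1e-9:
        n_eff = int(band.segment_length / coarsest + 1e-9)
        if n_eff < 2 * int(band.freq_indices[-1]):
            raise InvalidArgumentError(
                f"signal sampled at {coarsest:g} s cannot resolve the "
                f"{band.f_lo:g}-{band.f_hi:g} Hz band")
        return n_eff, coarsest
    return band.n_samples, band.dt


def _segment_starts(band: Band, dt_eff: float) -> np.ndarray:
    """Segment start times snapped onto the effective sampling grid."""
    t = np.arange(band.n_segments) * band.segment_length
    return np.round(t / dt_eff) * dt_eff


def _segment_matrix_spikes(spikes: SpikeTrain, band: Band,
                           layout: Optional[Tuple[int, float]] = None) -> np.ndarray:
    """Binned rate (spikes/s) of shape (n_segments, n_eff)."""
    n, dt = layout if layout is not None else (band.n_samples, band.dt)
    m = band.n_segments
    starts = _segment_starts(band, dt)
    total_bins = int(round(starts[-1] / dt)) + n
    edges = np.arange(total_bins + 1) * dt
    counts, _ = np.histogram(spikes.times, bins=edges)
    idx = np.round(starts / dt).astype(np.int64)
    return counts[idx[:, None] + np.arange(n)] / dt


def _segment_matrix_signal(signal: ContinuousSignal, band: Band,
                           layout: Optional[Tuple[int, float]] = None) -> np.ndarray:
    """Bin-averaged signal segments of shape (n_segments, n_eff).

    The integrate-and-average extraction is exact (a pure gather) when the
    segment grid coincides with the signal's native grid.
    """
    n, dt = layout if layout is not None else _band_layout(band, [signal.dt])
    m = band.n_segments
    starts = _segment_starts(band, dt)
    span = starts[-1] + n * dt
    if signal.duration + signal.dt + 1e-9 < span:
        raise InvalidArgumentError(
            f"signal ({signal.duration:g} s) shorter than the segmented span "
            f"({span:g} s) of the {band.f_lo:g}-{band.f_hi:g} Hz band")
    cum = np.concatenate([[0.0], np.cumsum(signal.values) * signal.dt])
    grid = signal.t0 + np.arange(signal.n + 1) * signal.dt
    edges = starts[:, None] + np.arange(n + 1) * dt
    c = np.interp(edges.ravel(), grid, cum).reshape(m, n + 1)
    return np.diff(c, axis=1) / dt


def _band_auto_power(segs: np.ndarray, band: Band, taper: TaperParams,
                     dt: Optional[float] = None) -> np.ndarray:
    """Mean over segments and tapers of the tapered periodogram at the band
    frequencies.  Returns the two-sided density (len(band.freq_indices),)."""
    n = segs.shape[1]
    dt = band.segment_length / n if dt is None else dt
    h = _tapers(n, taper.nw, taper.k)
    x = segs - segs.mean(axis=1, keepdims=True)
    idx = band.freq_indices
    acc = np.zeros(idx.size)
    for hk in h:
        f = np.fft.rfft(hk * x, axis=1)[:, idx]
        acc += np.mean(np.abs(f) ** 2, axis=0)
    corr = _demean_correction(n, taper.nw, taper.k)[:, idx].sum(axis=0)
    return dt * acc / corr


def _chi2_ci(power: np.ndarray, dof: np.ndarray, ci: float) -> Tuple[np.ndarray, np.ndarray]:
    a = (1.0 - ci) / 2.0
    lo = power * dof / stats.chi2.ppf(1 - a, dof)
    hi = power * dof / stats.chi2.ppf(a, dof)
    return lo, hi


def _assemble(
    per_band: Sequence[np.ndarray], plan: SegmentationPlan, taper: TaperParams, ci: float
) -> Tuple[np.ndarray, ...]:
    freqs = np.concatenate([b.frequencies for b in reversed(plan.bands)])
    power = np.concatenate(list(reversed(per_band)))
    n_seg = np.concatenate(
        [np.full(b.frequencies.size, b.n_segments) for b in reversed(plan.bands)]
    )
    dof = 2.0 * taper.k * n_seg
    lo, hi = _chi2_ci(power, dof, ci)
    return freqs, power, lo, hi, n_seg, dof


def spiketrain_psd(
    spikes: SpikeTrain,
    plan: SegmentationPlan,
    taper: TaperParams = TaperParams(),
    ci: float = 0.95,
) -> SpectrumEstimate:
    """Segmented multitaper power spectrum of a spike train.

    Spikes are counted on a uniform grid within each segment (1 ms for fast
    bands, coarser for infraslow ones — the band only uses its lowest
    Fourier bins, and binning leaves the white mu floor of a point process
    exact), each segment is mean-subtracted, tapered and averaged.
    """
    if spikes.n_spikes == 0:
        raise EmptyInputError("empty spike train")
    per_band = [_band_auto_power(_segment_matrix_spikes(spikes, b), b, taper) for b in plan.bands]
    freqs, power, lo, hi, n_seg, dof = _assemble(per_band, plan, taper, ci)
    meta = {"taper": taper, "ci": ci, "low_spike_count": spikes.n_spikes < 100}
    return SpectrumEstimate(freqs, power, lo, hi, n_seg, dof, mu=spikes.rate, meta=meta)


def continuous_psd(
    signal: ContinuousSignal,
    plan: SegmentationPlan,
    taper: TaperParams = TaperParams(),
    ci: float = 0.95,
) -> SpectrumEstimate:
    """Segmented multitaper power spectrum of a continuous signal."""
    per_band = []
    for b in plan.bands:
        layout = _band_layout(b, [signal.dt])
        segs = _segment_matrix_signal(signal, b, layout)
        per_band.append(_band_auto_power(segs, b, taper, dt=layout[1]))
    freqs, power, lo, hi, n_seg, dof = _assemble(per_band, plan, taper, ci)
    return SpectrumEstimate(freqs, power, lo, hi, n_seg, dof, meta={"taper": taper, "ci": ci})


def whole_recording_psd(
    x: Union[SpikeTrain, ContinuousSignal],
    f_max: float = 0.01,
    dt: float = 1.0,
    taper: TaperParams = TaperParams(),
    ci: float = 0.95,
) -> SpectrumEstimate:
    """Single-segment multitaper spectrum of the entire recording, for
    frequencies below the segmented range (``< 0.01`` Hz by default)."""
    if isinstance(x, SpikeTrain):
        sig = x.binned(dt)
        mu = x.rate
    else:
        sig, mu = x, None
    n = sig.n
    band = Band(f_lo=1.0 / sig.duration / 2, f_hi=f_max, segment_length=sig.duration,
                n_segments=1, n_samples=n)
    segs = sig.values[np.newaxis, :]
    h = _tapers(n, taper.nw, taper.k)
    xdm = segs - segs.mean()
    freqs_all = np.fft.rfftfreq(n, sig.dt)
    keep = (freqs_all > 0) & (freqs_all < f_max)
    acc = np.zeros(keep.sum())
    for hk in h:
        f = np.fft.rfft(hk * xdm, axis=1)[:, keep]
        acc += np.abs(f[0]) ** 2
    power = sig.dt * acc / h.shape[0]
    dof = np.full(power.size, 2.0 * taper.k)
    lo, hi = _chi2_ci(power, dof, ci)
    return SpectrumEstimate(freqs_all[keep], power, lo, hi,
                            np.ones(power.size, dtype=int), dof, mu=mu,
                            meta={"taper": taper, "ci": ci, "whole_recording": True})


def fit_power_law(
    spectrum: SpectrumEstimate,
    band: Tuple[float, float] = (0.01, 1.0),
    mode: str = "power",
) -> PowerLawFit:
    """Fit ``const / f**beta`` to the spectrum over ``band`` (log-log OLS).

    ``mode='power'`` fits the spectrum as-is (the convention used for
    spike-train spectra in the source analysis); ``mode='excess'`` fits
    ``max(Snn - mu, 1e-6 * mu)``, targeting the intensity spectrum S_ll,
    which removes the downward bias of the white mu floor when recovering
    the exponent of the underlying rate process.
    """
    f = spectrum.frequencies
    sel = (f >= band[0]) & (f <= band[1])
    if sel.sum() < 5:
        raise FitFailureError(f"fewer than 5 frequencies in band {band}")
    y = spectrum.power[sel].copy()
    if mode == "excess":
        if spectrum.mu is None:
            raise InvalidArgumentError("mode='excess' requires a point-process spectrum")
        y = np.maximum(y - spectrum.mu, 1e-6 * spectrum.mu)
    elif mode != "power":
        raise InvalidArgumentError("mode must be 'power' or 'excess'")
    x = f[sel]
    good = y > 0
    if good.sum() < 5:
        raise FitFailureError("fewer than 5 positive power values in band")
    lx, ly = np.log(x[good]), np.log(y[good])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(beta=-slope, const=float(np.exp(intercept)),
                       fit_band=(float(x[good].min()), float(x[good].max())),
                       r_squared=float(r2), n_points=int(good.sum()))


def population_rate(
    recording: Recording,
    target_unit: int,
    bin: float = 1e-3,
    exclusion_um: float = 60.0,
) -> ContinuousSignal:
    """Summed spike rate of all units except those near the target unit.

    With more than one shank present, all units on the target's shank are
    excluded; on a single-shank probe, units within ``exclusion_um``
    micrometres of the target's depth are excluded.
    """
    units = recording.units
    if not 0 <= target_unit < len(units):
        raise InvalidArgumentError("target_unit out of range")
    target = units[target_unit]
    multi_shank = len(set(u.shank for u in units)) > 1
    if multi_shank:
        included = [u for u in units if u.shank != target.shank]
        mode = "shank"
    else:
        included = [
            u for i, u in enumerate(units)
            if i != target_unit and abs(u.depth_um - target.depth_um) > exclusion_um
        ]
        mode = "depth"
    if len(included) < 1:
        raise ExclusionEmptyError("no units remain after exclusion")
    n = int(round(recording.duration / bin))
    edges = np.linspace(0.0, n * bin, n + 1)
    counts = np.zeros(n)
    for u in included:
        counts += np.histogram(u.times, bins=edges)[0]
    sig = ContinuousSignal(counts / bin, bin)
    sig.meta.update(exclusion_mode=mode, n_units=len(included),
                    total_spikes=int(sum(u.n_spikes for u in included)))
    return sig


def psd_sum_ratio(
    pop_spectrum: SpectrumEstimate, unit_spectra: Sequence[SpectrumEstimate]
) -> np.ndarray:
    """Ratio of the population-rate PSD to the sum of unit PSDs, per frequency.

    For independent units the ratio is ~1 everywhere; shared slow drive
    pushes it above 1 in the infraslow range.
    """
    f = pop_spectrum.frequencies
    total = np.zeros_like(pop_spectrum.power)
    for s in unit_spectra:
        if s.frequencies.shape != f.shape or not np.allclose(s.frequencies, f, rtol=1e-6):
            raise InvalidArgumentError("unit spectrum frequency grid mismatch")
        total += s.power
    return pop_spectrum.power / total


def powerlaw_power_fraction(beta: float, ratio: float = 0.5) -> float:
    """For a ``1/f**beta`` spectrum (beta < 1), the fraction of the power
    below a frequency ``omega`` that lies below ``ratio * omega``:
    ``ratio**(1 - beta)``.  For beta = 0.4 and ratio 1/2 this is ~0.66."""
    if not 0 <= beta < 1:
        raise InvalidArgumentError("requires 0 <= beta < 1 for integrable low end")
    if not 0 < ratio < 1:
        raise InvalidArgumentError("ratio must be in (0, 1)")
    return ratio ** (1.0 - beta)
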