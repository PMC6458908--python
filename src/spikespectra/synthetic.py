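"""Synthetic populations of doubly-stochastic Poisson spike trains.

The generator emulates the statistical structure the downstream analysis
assumes: each neuron is a Poisson process whose intensity lambda(t) follows
an exponential link on a weighted sum of latent signals —

* a private power-law latent (``const/f**beta``, beta in 0.2-0.6) giving the
  neuron scale-free infraslow rate fluctuations,
* a shared infraslow "arousal" latent, to which ~70% of neurons couple in
  phase and ~30% in antiphase,
* a shared fast latent with positive (near-zero-phase) coupling for all
  neurons,

plus a 2 ms hard refractory period and a pupil surrogate: the low-passed
shared slow latent delayed so that spiking leads the pupil by ~0.78 rad at
0.03 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sp_signal

from .core import ContinuousSignal, InvalidArgumentError, Recording, SpikeTrain

__all__ = [
    "LatentSpec",
    "NeuronSpec",
    "SyntheticRecording",
    "generate_powerlaw_signal",
    "intensity_from_latents",
    "sample_spike_train",
    "generate_population",
    "DEFAULT_PUPIL_LAG",
]

#: delay of the pupil surrogate behind spiking: 0.78 rad lead at 0.03 Hz
DEFAULT_PUPIL_LAG = 0.78 / (2 * math.pi * 0.03)


@dataclass(frozen=True)
class LatentSpec:
    """Band-limited power-law latent: ``S(f) ~ const / f**beta`` within ``band``.

    The band extends well below the 0.01 Hz analysis floor by default:
    cortical rate fluctuations are scale-free down to the recording length,
    and power below ~0.01 Hz is what drives spike-count dispersion in
    minute-long bins.
    """

    beta: float = 0.4
    band: Tuple[float, float] = (1e-4, 1.0)
    variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise InvalidArgumentError("beta must be >= 0")
        if not (0 < self.band[0] < self.band[1]):
            raise InvalidArgumentError("band must satisfy 0 < lo < hi")
        if self.variance <= 0:
            raise InvalidArgumentError("variance must be positive")


@dataclass(frozen=True)
class NeuronSpec:
    """Per-neuron parameters of the doubly-stochastic model.

    ``slow_coupling`` is a signed weight on the shared slow latent (negative
    = antiphase with arousal); ``fast_coupling`` is a nonnegative weight on
    the shared fast latent; ``beta`` is the exponent of the neuron's private
    power-law latent and ``private_weight`` its (log-intensity) weight.
    ``slow_delay`` shifts the neuron's copy of the slow latent in time
    (seconds; positive = the neuron follows arousal later), giving the
    population the within-mode spread of infraslow phase preferences that
    recorded cortical neurons show.
    """

    mean_rate: float = 5.0
    beta: float = 0.4
    slow_coupling: float = 0.5
    fast_coupling: float = 0.2
    private_weight: float = 0.4
    refractory: float = 2e-3
    slow_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise InvalidArgumentError("mean_rate must be positive")
        if self.refractory < 0:
            raise InvalidArgumentError("refractory must be >= 0")
        if self.fast_coupling < 0:
            raise InvalidArgumentError("fast_coupling must be >= 0")


@dataclass
class SyntheticRecording(Recording):
    """A generated population with its latents, pupil surrogate and specs."""

    latents: Optional[Tuple[ContinuousSignal, ContinuousSignal]] = None
    neuron_specs: List[NeuronSpec] = field(default_factory=list)
    seed: int = 0


def generate_powerlaw_signal(
    spec: LatentSpec, duration: float, dt: float
) -> ContinuousSignal:
    """Zero-mean signal whose spectrum is ``const/f**beta`` inside ``spec.band``
    and zero outside (Fourier-domain shaping with random phases).

    The sample variance is normalised to ``spec.variance`` exactly; the
    output is a deterministic function of ``spec.seed``.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    n = int(round(duration / dt))
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples")
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(n, dt)
    amp = np.zeros(freqs.size)
    in_band = (freqs >= spec.band[0]) & (freqs <= spec.band[1])
    if not np.any(in_band):
        raise InvalidArgumentError("no Fourier frequencies inside the latent band")
    amp[in_band] = freqs[in_band] ** (-spec.beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    if sd > 0:
        x *= math.sqrt(spec.variance) / sd
    return ContinuousSignal(x, dt, meta={"spec": spec})


def intensity_from_latents(
    neuron: NeuronSpec,
    slow: ContinuousSignal,
    fast: ContinuousSignal,
    private: Optional[ContinuousSignal] = None,
) -> ContinuousSignal:
    """Nonnegative rate intensity via an exponential link on the latents.

    ``log lambda = slow_coupling * slow + fast_coupling * fast +
    private_weight * private + const``; the constant renormalises the time
    average to ``neuron.mean_rate`` exactly, so two neurons with the same
    couplings and rates mu and 2 mu have sample-by-sample proportional
    intensities.
    """
    if not slow.same_grid(fast):
        raise InvalidArgumentError("slow and fast latents must share the sampling grid")
    s_vals = slow.values
    if neuron.slow_delay != 0.0:
        s_vals = np.roll(s_vals, int(round(neuron.slow_delay / slow.dt)))
    g = neuron.slow_coupling * s_vals + neuron.fast_coupling * fast.values
    if private is not None:
        if not slow.same_grid(private):
            raise InvalidArgumentError("private latent grid mismatch")
        g = g + neuron.private_weight * private.values
    lam = np.exp(g - g.max())  # subtract max before exp for numerical safety
    lam *= neuron.mean_rate / lam.mean()
    return ContinuousSignal(lam, slow.dt, t0=slow.t0)


def sample_spike_train(
    intensity: ContinuousSignal,
    refractory: float = 0.0,
    seed: int = 0,
    **unit_kwargs,
) -> SpikeTrain:
    """Inhomogeneous Poisson sampling from a rate intensity, with dead time.

    Counts are drawn per grid bin, spike times jittered uniformly within
    the bin, and spikes closer than ``refractory`` to the previous accepted
    spike are deleted (dead-time thinning).
    """
    lam = intensity.values
    if np.any(lam < 0):
        raise InvalidArgumentError("intensity must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam * intensity.dt)
    total = int(counts.sum())
    starts = intensity.t0 + np.repeat(np.arange(lam.size), counts) * intensity.dt
    times = np.sort(starts + rng.random(total) * intensity.dt)
    if refractory > 0 and times.size > 1:
        times = _dead_time(times, refractory)
    return SpikeTrain(times, duration=intensity.t0 + intensity.duration, **unit_kwargs)


def _dead_time(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy deletion of spikes within ``refractory`` of the last kept one."""
    keep = np.ones(times.size, dtype=bool)
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last < refractory:
            keep[i] = False
        else:
            last = times[i]
    return times[keep]


def generate_independent_neurons(
    n_neurons: int = 20,
    duration: float = 7200.0,
    beta: float = 0.4,
    rate_range: Tuple[float, float] = (1.0, 10.0),
    coupling_range: Tuple[float, float] = (0.6, 1.2),
    seed: int = 0,
    dt: float = 0.01,
) -> List[Tuple[SpikeTrain, NeuronSpec]]:
    """Independent doubly-stochastic neurons for single-train analyses.

    Each neuron gets its own power-law latent with exponent ``beta``, a
    rate drawn log-uniformly from ``rate_range`` and a log-intensity
    coupling weight from ``coupling_range`` (the default depth puts
    spike-count Fano factors at minute bins severalfold above the
    ISI-shuffled level, the regime the analysis targets), plus a 2 ms
    refractory period.
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(1 + 2 * n_neurons)]
    rng = np.random.default_rng(seeds[0])
    out = []
    zero = None
    for i in range(n_neurons):
        mu = float(np.exp(rng.uniform(*np.log(rate_range))))
        w = float(rng.uniform(*coupling_range))
        spec = NeuronSpec(mean_rate=mu, beta=beta, slow_coupling=0.0,
                          fast_coupling=0.0, private_weight=w, refractory=2e-3)
        latent = generate_powerlaw_signal(
            LatentSpec(beta=beta, band=(1e-4, 1.0), seed=seeds[1 + 2 * i]),
            duration, dt)
        if zero is None or zero.n != latent.n:
            zero = ContinuousSignal(np.zeros(latent.n), dt)
        lam = intensity_from_latents(spec, zero, zero, private=latent)
        train = sample_spike_train(lam, refractory=spec.refractory,
                                   seed=seeds[2 + 2 * i], unit_id=f"u{i:03d}")
        out.append((train, spec))
    return out


def _pupil_surrogate(
    slow: ContinuousSignal, lag: float, dt_out: float = 0.1, cutoff: float = 0.2
) -> ContinuousSignal:
    """Second-order zero-phase low-pass of the slow latent plus a pure delay."""
    coarse = slow.resampled(dt_out)
    b, a = sp_signal.butter(2, cutoff, fs=1.0 / dt_out)
    filtered = sp_signal.filtfilt(b, a, coarse.values)
    shift = int(round(lag / dt_out))
    if shift > 0:
        delayed = np.concatenate([np.full(shift, filtered[0]), filtered[:-shift]])
    else:
        delayed = filtered
    return ContinuousSignal(delayed, dt_out, meta={"lag_s": lag, "cutoff_hz": cutoff})


def generate_population(
    n_neurons: int = 40,
    duration: float = 7200.0,
    slow_spec: Optional[LatentSpec] = None,
    fast_spec: Optional[LatentSpec] = None,
    antiphase_fraction: float = 0.3,
    pupil_lag: float = DEFAULT_PUPIL_LAG,
    seed: int = 0,
    dt: float = 1e-3,
    n_shanks: int = 4,
) -> SyntheticRecording:
    """Generate the default desk-scale scene: a population of coupled
    doubly-stochastic neurons plus latents and a pupil surrogate.

    ``round(antiphase_fraction * n_neurons)`` neurons receive a negative
    slow coupling.  Units are spread over ``n_shanks`` shanks with 20 um
    depth spacing within a shank.
    """
    if n_neurons < 2:
        raise InvalidArgumentError("population rate undefined for < 2 neurons")
    if not 0 <= antiphase_fraction <= 1:
        raise InvalidArgumentError("antiphase_fraction must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3 + 3 * n_neurons)]
    rng = np.random.default_rng(seeds[0])

    if slow_spec is None:
        slow_spec = LatentSpec(beta=0.4, band=(1e-4, 0.5), variance=1.0, seed=seeds[1])
    if fast_spec is None:
        fast_spec = LatentSpec(beta=0.0, band=(1.0, 30.0), variance=1.0, seed=seeds[2])
    slow = generate_powerlaw_signal(slow_spec, duration, dt)
    fast = generate_powerlaw_signal(fast_spec, duration, dt)

    n_anti = int(round(antiphase_fraction * n_neurons))
    anti = np.zeros(n_neurons, dtype=bool)
    anti[rng.permutation(n_neurons)[:n_anti]] = True

    specs, units = [], []
    for i in range(n_neurons):
        rate = float(np.clip(rng.lognormal(mean=math.log(4.0), sigma=0.6), 0.5, 20.0))
        w_slow = rng.uniform(0.4, 0.8) * (-1.0 if anti[i] else 1.0)
        w_fast = rng.uniform(0.1, 0.3)
        beta_i = rng.uniform(0.2, 0.6)
        spec = NeuronSpec(mean_rate=rate, beta=beta_i, slow_coupling=float(w_slow),
                          fast_coupling=float(w_fast), private_weight=0.4,
                          refractory=2e-3,
                          slow_delay=float(rng.normal(0.0, 3.0)))
        private = generate_powerlaw_signal(
            LatentSpec(beta=beta_i, band=(1e-4, 1.0), variance=1.0,
                       seed=seeds[3 + 3 * i]),
            duration, dt)
        lam = intensity_from_latents(spec, slow, fast, private=private)
        unit = sample_spike_train(
            lam, refractory=spec.refractory, seed=seeds[4 + 3 * i],
            unit_id=f"u{i:03d}", shank=i % n_shanks,
            depth_um=400.0 + 20.0 * (i // n_shanks))
        specs.append(spec)
        units.append(unit)

    pupil = _pupil_surrogate(slow, pupil_lag)
    return SyntheticRecording(units=units, duration=duration, pupil=pupil,
                              latents=(slow, fast), neuron_specs=specs, seed=seed)
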