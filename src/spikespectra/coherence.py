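"""Coherency between spike trains and continuous signals, with the
rate-adjustment correction.

Coherence between a continuous process y(t) and a spike train n(t) with
doubly-stochastic intensity lambda(t) of rate mu obeys

    C_yn(w) = C_yl(w) * (1 + mu / S_ll(w))**(-1/2),

so the measured spike coherence depends on the neuron's rate even when the
underlying intensities are proportional.  The rate-adjusted coherence
rescales to a reference rate of 1 spike/s with the correction factor
``(1 + (mu - 1) * mu / Snn(w))**(-1/2)``, computable from the spike-train
spectrum alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core import ContinuousSignal, EmptyInputError, InvalidArgumentError, SpikeTrain
from .spectral import (
    Band,
    SegmentationPlan,
    SpectrumEstimate,
    TaperParams,
    _band_layout,
    _segment_matrix_signal,
    _segment_matrix_spikes,
    _tapers,
)

__all__ = [
    "CoherencyEstimate",
    "CrossSpectralSuite",
    "cross_spectral_suite",
    "coherency_spectrum",
    "predicted_coherence",
    "rate_adjust",
    "pair_dominance",
    "PROBE_FREQUENCIES",
]

#: probe frequencies (Hz) for pairwise dominance comparisons
PROBE_FREQUENCIES = (0.01, 0.03, 0.1, 0.32, 1.0, 3.2, 10.0, 32.0, 100.0)


@dataclass
class CoherencyEstimate:
    """Per-frequency coherence magnitude, phase and significance.

    ``rate_adjusted`` is filled by :func:`rate_adjust`; ``phase`` follows
    the convention that a positive phase means the unit leads the signal.
    """

    frequencies: np.ndarray
    coherence: np.ndarray
    phase: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    dof: np.ndarray
    mu: Optional[float] = None
    rate_adjusted: Optional[np.ndarray] = None
    adjusted_clipped: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class CrossSpectralSuite:
    """Everything the segmented cross-spectral estimation produces at once:
    auto-spectra, coherency, and per-segment phases (for circular phase
    statistics)."""

    frequencies: np.ndarray
    s_xx: np.ndarray
    s_yy: np.ndarray
    s_xy: np.ndarray
    coherence: np.ndarray
    phase: np.ndarray
    n_segments: np.ndarray
    dof: np.ndarray
    segment_phases: List[np.ndarray]
    mu: Optional[float]


def _band_cross(
    x_segs: np.ndarray, y_segs: np.ndarray, band: Band, taper: TaperParams,
    dt: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-band auto/cross spectra and per-segment cross phases."""
    n = x_segs.shape[1]
    dt = band.segment_length / n if dt is None else dt
    h = _tapers(n, taper.nw, taper.k)
    idx = band.freq_indices
    x = x_segs - x_segs.mean(axis=1, keepdims=True)
    y = y_segs - y_segs.mean(axis=1, keepdims=True)
    sxx = np.zeros(idx.size)
    syy = np.zeros(idx.size)
    sxy = np.zeros(idx.size, dtype=complex)
    seg_cross = np.zeros((x.shape[0], idx.size), dtype=complex)
    for hk in h:
        fx = np.fft.rfft(hk * x, axis=1)[:, idx]
        fy = np.fft.rfft(hk * y, axis=1)[:, idx]
        sxx += np.sum(np.abs(fx) ** 2, axis=0)
        syy += np.sum(np.abs(fy) ** 2, axis=0)
        cross = fx * np.conj(fy)
        sxy += np.sum(cross, axis=0)
        seg_cross += cross
    norm = dt / (x.shape[0] * h.shape[0])
    return sxx * norm, syy * norm, sxy * norm, np.angle(seg_cross)


def cross_spectral_suite(
    spikes: Union[SpikeTrain, ContinuousSignal],
    signal: ContinuousSignal,
    plan: SegmentationPlan,
    taper: TaperParams = TaperParams(),
) -> CrossSpectralSuite:
    """Segmented multitaper cross-spectral estimation between a spike train
    (or a continuous series) and a continuous signal."""
    if isinstance(spikes, SpikeTrain):
        if spikes.n_spikes == 0:
            raise EmptyInputError("empty spike train")
        mu = spikes.rate
        native = [signal.dt]
        seg_x = lambda band, layout: _segment_matrix_spikes(spikes, band, layout)
    else:
        mu = None
        native = [spikes.dt, signal.dt]
        seg_x = lambda band, layout: _segment_matrix_signal(spikes, band, layout)
    freqs, sxx_all, syy_all, sxy_all = [], [], [], []
    nseg_all, seg_phases = [], []
    for band in reversed(plan.bands):
        layout = _band_layout(band, native)
        xs = seg_x(band, layout)
        ys = _segment_matrix_signal(signal, band, layout)
        sxx, syy, sxy, ph = _band_cross(xs, ys, band, taper, dt=layout[1])
        freqs.append(band.frequencies)
        sxx_all.append(sxx)
        syy_all.append(syy)
        sxy_all.append(sxy)
        nseg_all.append(np.full(band.frequencies.size, band.n_segments))
        seg_phases.extend(ph.T)
    freqs = np.concatenate(freqs)
    sxx = np.concatenate(sxx_all)
    syy = np.concatenate(syy_all)
    sxy = np.concatenate(sxy_all)
    n_seg = np.concatenate(nseg_all)
    denom = np.sqrt(np.maximum(sxx * syy, 1e-300))
    coh = np.clip(np.abs(sxy) / denom, 0.0, 1.0)
    phase = np.angle(sxy)
    dof = 2.0 * taper.k * n_seg
    return CrossSpectralSuite(freqs, sxx, syy, sxy, coh, phase, n_seg, dof,
                              seg_phases, mu)


def _coherence_ci(coh: np.ndarray, dof: np.ndarray, ci: float
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Asymptotic CI on coherence magnitude via the Fisher z transform with
    SE = 1/sqrt(dof - 2)."""
    z = np.arctanh(np.clip(coh, 0.0, 1.0 - 1e-12))
    se = 1.0 / np.sqrt(np.maximum(dof - 2.0, 1.0))
    q = stats.norm.ppf((1 + ci) / 2)
    return np.tanh(np.maximum(z - q * se, 0.0)), np.tanh(z + q * se)


def coherence_significance_threshold(dof: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Null (zero-coherence) threshold: C = sqrt(1 - alpha**(1/(dof/2 - 1)))."""
    m = np.maximum(dof / 2.0 - 1.0, 1.0)
    return np.sqrt(1.0 - alpha ** (1.0 / m))


def coherency_spectrum(
    spikes: Union[SpikeTrain, ContinuousSignal],
    signal: ContinuousSignal,
    plan: SegmentationPlan,
    taper: TaperParams = TaperParams(),
    ci: float = 0.95,
    alpha: float = 0.05,
) -> CoherencyEstimate:
    """Segmented multitaper coherency between a unit and a continuous signal."""
    suite = cross_spectral_suite(spikes, signal, plan, taper)
    lo, hi = _coherence_ci(suite.coherence, suite.dof, ci)
    thresh = coherence_significance_threshold(suite.dof, alpha)
    return CoherencyEstimate(
        frequencies=suite.frequencies,
        coherence=suite.coherence,
        phase=suite.phase,
        ci_low=lo,
        ci_high=hi,
        significant=suite.coherence > thresh,
        dof=suite.dof,
        mu=suite.mu,
        meta={"taper": taper, "ci": ci, "alpha": alpha},
    )


def predicted_coherence(
    c_intensity: Union[float, np.ndarray],
    mu: float,
    s_lambda: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Spike-train coherence predicted from the intensity coherence:
    ``C_yn = C_yl * (1 + mu / S_ll)**(-1/2)`` (0 where S_ll = 0)."""
    c = np.asarray(c_intensity, float)
    s = np.asarray(s_lambda, float)
    if np.any(c < 0) or np.any(c > 1) or mu < 0 or np.any(s < 0):
        raise InvalidArgumentError("require 0 <= C <= 1, mu >= 0, S_ll >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(s > 0, c / np.sqrt(1.0 + mu / np.maximum(s, 1e-300)), 0.0)
    return float(out) if out.ndim == 0 else out


def rate_adjust(estimate: CoherencyEstimate, snn: SpectrumEstimate) -> CoherencyEstimate:
    """Rate-adjusted coherence: what the unit would show at 1 spike/s with a
    proportional intensity, via ``C * (1 + (mu-1)*mu/Snn)**(-1/2)``."""
    if estimate.mu is None or estimate.mu <= 0:
        raise InvalidArgumentError("rate adjustment needs a spike-train estimate with mu > 0")
    f = estimate.frequencies
    if snn.frequencies.shape != f.shape or not np.allclose(snn.frequencies, f, rtol=1e-6):
        raise InvalidArgumentError("Snn frequency grid mismatch")
    mu = estimate.mu
    # for mu < 1 the correction boosts coherence and the base can reach 0
    # when Snn < (1 - mu) * mu; clamp and let the [0, 1] clip flag it
    base = np.maximum(1.0 + (mu - 1.0) * mu / np.maximum(snn.power, 1e-300), 1e-12)
    factor = 1.0 / np.sqrt(base)
    raw = estimate.coherence * factor
    clipped = bool(np.any(raw > 1.0))
    adjusted = np.clip(raw, 0.0, 1.0)
    new = replace(estimate)
    new.rate_adjusted = adjusted
    new.adjusted_clipped = clipped
    new.ci_low = np.clip(estimate.ci_low * factor, 0.0, 1.0)
    new.ci_high = np.clip(estimate.ci_high * factor, 0.0, 1.0)
    new.meta = dict(estimate.meta, rate_adjusted=True)
    return new


def _probe_index(freqs: np.ndarray, f0: float) -> int:
    i = int(np.argmin(np.abs(np.log(freqs) - np.log(f0))))
    if abs(np.log(freqs[i] / f0)) > np.log(1.25):
        raise InvalidArgumentError(f"no analysis frequency near probe {f0} Hz")
    return i


def pair_dominance(
    a: CoherencyEstimate,
    b: CoherencyEstimate,
    probe_frequencies: Sequence[float] = PROBE_FREQUENCIES,
    alpha: float = 0.001,
) -> str:
    """Compare two units' rate-adjusted coherences at the probe frequencies.

    The null "a >= b at all probes" is rejected when b significantly
    exceeds a at some probe (one-sided Z-test on Fisher-transformed
    magnitudes, Bonferroni-corrected for the number of probes), and vice
    versa.  Returns ``'crossed'`` when both nulls are rejected,
    ``'a_dominates'`` / ``'b_dominates'`` when one unit is significantly
    stronger somewhere and never significantly weaker, else
    ``'undetermined'``.
    """
    ca = a.rate_adjusted if a.rate_adjusted is not None else a.coherence
    cb = b.rate_adjusted if b.rate_adjusted is not None else b.coherence
    corrected = alpha / len(probe_frequencies)
    a_gt, b_gt = False, False
    for f0 in probe_frequencies:
        ia = _probe_index(a.frequencies, f0)
        ib = _probe_index(b.frequencies, f0)
        za = np.arctanh(min(ca[ia], 1 - 1e-12))
        zb = np.arctanh(min(cb[ib], 1 - 1e-12))
        se = np.sqrt(1.0 / max(a.dof[ia] - 2, 1) + 1.0 / max(b.dof[ib] - 2, 1))
        z = (za - zb) / se
        if stats.norm.sf(z) <= corrected:
            a_gt = True
        if stats.norm.cdf(z) <= corrected:
            b_gt = True
    if a_gt and b_gt:
        return "crossed"
    if a_gt:
        return "a_dominates"
    if b_gt:
        return "b_dominates"
    return "undetermined"
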