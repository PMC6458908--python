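"""Phase spectra of units versus population rate or pupil, and the
linearity / logarithmicity indices of phase-versus-frequency curves.

Phases are estimated segment-wise (the same segmentation as the coherence),
summarised by the circular mean and SD, and assigned only where the
segment-phase distribution has a statistically significant mean direction
(Rayleigh test, P <= 0.05).  A positive phase means the unit leads the
signal; a unit lagging the population rate by a quarter cycle has phase
-pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from pingouin.circular import circ_rayleigh
from scipy import stats

from .core import (
    ContinuousSignal,
    InsufficientDataError,
    InvalidArgumentError,
    SpikeTrain,
)
from .spectral import SegmentationPlan, TaperParams
from .coherence import cross_spectral_suite

__all__ = [
    "PhaseSpectrum",
    "PhaseIndices",
    "PhaseDistributionSummary",
    "phase_spectrum",
    "phase_distribution_summary",
    "longest_valid_interval",
    "linearity_index",
    "logarithmicity_index",
    "phase_indices",
    "phase_model_comparison",
    "circular_diameter",
    "wrap_angle",
]


def wrap_angle(phi: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def resultant_length(phases: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def circular_diameter(phases: np.ndarray) -> float:
    """Length of the smallest arc containing all the phases.

    Equals ``max - min`` unless the set wraps around +-pi, in which case
    the largest angular gap is excised instead.
    """
    p = np.sort(wrap_angle(np.asarray(phases, float)))
    if p.size < 2:
        return 0.0
    gaps = np.diff(np.concatenate([p, [p[0] + 2 * np.pi]]))
    return float(2 * np.pi - gaps.max())


@dataclass
class PhaseSpectrum:
    """Circular mean phase per frequency, defined only where significant."""

    frequencies: np.ndarray
    phase: np.ndarray
    circ_sd: np.ndarray
    defined: np.ndarray
    n_segments: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhaseIndices:
    """Linearity and logarithmicity of a phase spectrum on an interval.

    Both are ``log(diam upper half / diam lower half)`` of the phase set,
    the halves split at the arithmetic mean of the interval endpoints
    (linearity) or at their geometric mean (logarithmicity); ``valid`` is
    False when the interval spans less than a decade.
    """

    linearity: float
    logarithmicity: float
    interval: Optional[Tuple[float, float]]
    valid: bool


@dataclass
class PhaseDistributionSummary:
    """Fractions of units by preferred-phase category at one frequency."""

    n: int
    near_zero: float
    near_pi: float
    leading: float
    lagging: float

    def proportion_test(self, frac_a: str, frac_b: str) -> Tuple[float, float]:
        """Two-proportion Z-test between two named fractions; returns
        (z, two-sided p)."""
        pa, pb = getattr(self, frac_a), getattr(self, frac_b)
        pool = (pa + pb) / 2.0
        if pool in (0.0, 1.0):
            return 0.0, 1.0
        se = np.sqrt(pool * (1 - pool) * 2.0 / self.n)
        z = (pa - pb) / se
        return float(z), float(2 * stats.norm.sf(abs(z)))


def phase_spectrum(
    spikes: Union[SpikeTrain, ContinuousSignal],
    signal: ContinuousSignal,
    plan: SegmentationPlan,
    taper: TaperParams = TaperParams(),
    alpha: float = 0.05,
) -> PhaseSpectrum:
    """Segment-wise phase of a unit with respect to a continuous signal.

    Per frequency, the phases of the per-segment cross-spectra are pooled;
    the circular mean is reported where a Rayleigh test on them rejects
    uniformity at ``alpha``, otherwise the frequency is marked undefined.
    """
    suite = cross_spectral_suite(spikes, signal, plan, taper)
    nf = suite.frequencies.size
    phase = np.full(nf, np.nan)
    sd = np.full(nf, np.nan)
    defined = np.zeros(nf, dtype=bool)
    for i in range(nf):
        seg_ph = suite.segment_phases[i]
        if seg_ph.size < 2:
            continue
        _, pval = circ_rayleigh(seg_ph)
        if pval <= alpha:
            defined[i] = True
            phase[i] = stats.circmean(seg_ph, high=np.pi, low=-np.pi)
            sd[i] = stats.circstd(seg_ph, high=np.pi, low=-np.pi)
    return PhaseSpectrum(suite.frequencies, phase, sd, defined,
                         suite.n_segments, meta={"alpha": alpha})


def phase_distribution_summary(phases: Sequence[float]) -> PhaseDistributionSummary:
    """Fractions of phases near 0 (|phi| <= pi/2), near pi, leading the
    signal (pi/4..3pi/4) and lagging it (-3pi/4..-pi/4)."""
    p = wrap_angle(np.asarray([x for x in phases if np.isfinite(x)], float))
    if p.size < 10:
        raise InsufficientDataError("need >= 10 defined phases")
    near_zero = np.mean(np.abs(p) <= np.pi / 2)
    near_pi = np.mean(np.abs(p) > np.pi / 2)
    leading = np.mean((p >= np.pi / 4) & (p <= 3 * np.pi / 4))
    lagging = np.mean((p <= -np.pi / 4) & (p >= -3 * np.pi / 4))
    return PhaseDistributionSummary(int(p.size), float(near_zero), float(near_pi),
                                    float(leading), float(lagging))


def longest_valid_interval(ps: PhaseSpectrum, min_decades: float = 1.0
                           ) -> Optional[Tuple[float, float]]:
    """Longest (in log-frequency) run of consecutive defined frequencies;
    None when the best run spans less than ``min_decades`` decades."""
    best = None
    best_span = -1.0
    i = 0
    d = ps.defined
    while i < d.size:
        if not d[i]:
            i += 1
            continue
        j = i
        while j + 1 < d.size and d[j + 1]:
            j += 1
        a, b = ps.frequencies[i], ps.frequencies[j]
        span = np.log10(b / a) if b > a else 0.0
        if span > best_span:
            best_span = span
            best = (float(a), float(b))
        i = j + 1
    if best is None or best_span < min_decades:
        return None
    return best


def _diam_ratio_index(ps: PhaseSpectrum, interval: Tuple[float, float],
                      k: float) -> float:
    a, b = interval
    if not (a < k < b):
        raise InvalidArgumentError("split point must lie inside the interval")
    f = ps.frequencies
    sel = ps.defined & (f >= a) & (f <= b)
    lower = ps.phase[sel & (f <= k)]
    upper = ps.phase[sel & (f >= k)]
    if lower.size < 2 or upper.size < 2:
        return float("nan")
    d_lo = circular_diameter(lower)
    d_hi = circular_diameter(upper)
    if d_lo == 0.0 or d_hi == 0.0:
        return float("nan")
    return float(np.log(d_hi / d_lo))


def linearity_index(ps: PhaseSpectrum, interval: Tuple[float, float]) -> float:
    """log of the phase-set diameter ratio above/below the arithmetic mean
    of the interval: 0 for phase changing on a linear scale, positive for
    supralinear, negative for sublinear.  NaN when a half is degenerate."""
    a, b = interval
    return _diam_ratio_index(ps, interval, (a + b) / 2.0)


def logarithmicity_index(ps: PhaseSpectrum, interval: Tuple[float, float]) -> float:
    """As :func:`linearity_index` but split at the geometric mean: 0 for
    phase changing on a logarithmic scale."""
    a, b = interval
    return _diam_ratio_index(ps, interval, float(np.sqrt(a * b)))


def phase_indices(ps: PhaseSpectrum, min_decades: float = 1.0) -> PhaseIndices:
    """Both indices evaluated on the longest well-defined interval."""
    interval = longest_valid_interval(ps, min_decades)
    if interval is None:
        return PhaseIndices(float("nan"), float("nan"), None, False)
    lin = linearity_index(ps, interval)
    logi = logarithmicity_index(ps, interval)
    return PhaseIndices(lin, logi, interval, np.isfinite(lin) and np.isfinite(logi))


def phase_model_comparison(
    phases_f0: np.ndarray, phases_f1: np.ndarray, f0: float, f1: float
) -> Tuple[float, float]:
    """Circular explained variance of phi(f1) under a constant-phase model
    (prediction phi(f0)) and a linear-phase / fixed-time-lag model
    (prediction phi(f0) * f1 / f0).

    EV = 1 - (1 - Rbar_resid) / (1 - Rbar_total), with Rbar the mean
    resultant length of the residual and of the raw phi(f1) distribution.
    """
    p0 = np.asarray(phases_f0, float)
    p1 = np.asarray(phases_f1, float)
    ok = np.isfinite(p0) & np.isfinite(p1)
    if ok.sum() < 10:
        raise InsufficientDataError("need >= 10 units with phases at both frequencies")
    p0, p1 = p0[ok], p1[ok]
    r_total = resultant_length(p1)
    if r_total >= 1.0 - 1e-12:
        raise InsufficientDataError("no phase dispersion to explain")

    def ev(pred: np.ndarray) -> float:
        r_resid = resultant_length(wrap_angle(p1 - pred))
        return float(1.0 - (1.0 - r_resid) / (1.0 - r_total))

    return ev(p0), ev(wrap_angle(p0 * f1 / f0))
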