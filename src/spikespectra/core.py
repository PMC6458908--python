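"""Core containers: spike trains, uniformly sampled signals, recordings.

A spike train is an ordered list of event times (seconds) — the point
process n(t).  A :class:`ContinuousSignal` is a uniformly sampled series —
population rate, pupil area, or a firing-rate intensity lambda(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "ContinuousSignal",
    "Recording",
    "InvalidArgumentError",
    "EmptyInputError",
    "InsufficientDurationError",
    "InsufficientDataError",
    "ExclusionEmptyError",
    "FitFailureError",
]


class InvalidArgumentError(ValueError):
    """An argument violates a precondition."""


class EmptyInputError(InvalidArgumentError):
    """An operation received an empty (or too small) spike train."""


class InsufficientDurationError(InvalidArgumentError):
    """The recording is too short for the requested frequency range."""


class InsufficientDataError(InvalidArgumentError):
    """Not enough observations for the requested statistic."""


class ExclusionEmptyError(InvalidArgumentError):
    """No units remain after applying the population-rate exclusion rule."""


class FitFailureError(RuntimeError):
    """A model fit could not be performed (e.g. too few valid points)."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit, with recording-site metadata.

    Parameters
    ----------
    times:
        Spike times in seconds, strictly increasing, within ``[0, duration]``.
    duration:
        Recording duration in seconds.
    unit_id:
        Identifier of the unit.
    shank:
        Shank / tetrode index the unit was recorded on.
    depth_um:
        Depth of the recording site in micrometres.
    """

    times: np.ndarray
    duration: float
    unit_id: str = "u0"
    shank: int = 0
    depth_um: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise InvalidArgumentError("spike times must be sorted")
            if t[0] < 0 or t[-1] > self.duration:
                raise InvalidArgumentError("spike times outside [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate mu in spikes/s."""
        return self.n_spikes / self.duration

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.times)

    def restricted(self, t0: float, t1: float) -> "SpikeTrain":
        """Spikes in ``[t0, t1)``, re-referenced to ``t0``."""
        sel = self.times[(self.times >= t0) & (self.times < t1)] - t0
        return replace(self, times=sel, duration=t1 - t0)

    def binned(self, dt: float, duration: Optional[float] = None) -> "ContinuousSignal":
        """Spike counts per second on a uniform grid of width ``dt``."""
        total = self.duration if duration is None else duration
        n = int(round(total / dt))
        edges = np.linspace(0.0, n * dt, n + 1)
        counts, _ = np.histogram(self.times, bins=edges)
        return ContinuousSignal(counts / dt, dt)


@dataclass
class ContinuousSignal:
    """Uniformly sampled series ``values[i]`` at times ``t0 + i*dt``."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidArgumentError("signal must be a 1-d array of >= 2 samples")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    def same_grid(self, other: "ContinuousSignal", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and np.isclose(self.dt, other.dt, rtol=rtol)
            and np.isclose(self.t0, other.t0, rtol=rtol, atol=1e-12)
        )

    def bin_average(self, edges: np.ndarray) -> np.ndarray:
        """Average of the signal over each ``[edges[i], edges[i+1])`` interval.

        Computed from the cumulative integral, so arbitrary (non-integer)
        ratios between ``dt`` and the bin width are handled exactly up to
        the piecewise-constant interpolation of the samples.
        """
        edges = np.asarray(edges, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.values) * self.dt])
        grid = self.t0 + np.arange(self.n + 1) * self.dt
        c = np.interp(edges, grid, cum)
        return np.diff(c) / np.diff(edges)

    def resampled(self, dt_new: float, n_new: Optional[int] = None) -> "ContinuousSignal":
        """Bin-averaged copy of the signal on a coarser (or equal) grid."""
        if n_new is None:
            n_new = int(self.duration / dt_new)
        edges = self.t0 + np.linspace(0.0, n_new * dt_new, n_new + 1)
        return ContinuousSignal(self.bin_average(edges), dt_new, t0=self.t0)


@dataclass
class Recording:
    """A set of simultaneously recorded units plus optional auxiliary signals."""

    units: Sequence[SpikeTrain]
    duration: float
    pupil: Optional[ContinuousSignal] = None

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise EmptyInputError("recording has no units")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def shanks(self) -> np.ndarray:
        return np.array([u.shank for u in self.units])
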