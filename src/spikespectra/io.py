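"""Plain-text I/O and analysis configuration.

Spike files are columnar text (CSV or TSV) with header
``unit_id, time_s, shank, depth_um``; continuous signals are two-column
``time_s, value`` files with uniform sampling.  Results are written as a
CSV table plus a JSON summary sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .core import ContinuousSignal, InvalidArgumentError, Recording, SpikeTrain
from .coherence import PROBE_FREQUENCIES

__all__ = [
    "AnalysisConfig",
    "read_spikes",
    "write_spikes",
    "read_signal",
    "write_signal",
    "write_results",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]


@dataclass
class AnalysisConfig:
    """All tunable parameters of the standard analysis, with the defaults
    of the reference procedure (0.01-100 Hz range, 2 ms refractory, 60 um
    single-shank exclusion radius, alpha 0.05 for phase significance and
    0.001 with Bonferroni x9 for pairwise dominance)."""

    f_min: float = 0.01
    f_max: float = 100.0
    probe_frequencies: Tuple[float, ...] = PROBE_FREQUENCIES
    taper_nw: float = 3.0
    taper_k: int = 5
    n_fano_bins: int = 18
    alpha_phase: float = 0.05
    alpha_dominance: float = 0.001
    refractory: float = 2e-3
    exclusion_um: float = 60.0
    powerlaw_band: Tuple[float, float] = (0.01, 1.0)
    pupil_frequency: float = 0.03
    fast_frequency: float = 10.0
    seed: int = 0
    # synthetic-scene parameters (used when no recording is supplied)
    n_neurons: int = 40
    duration: float = 7200.0
    antiphase_fraction: float = 0.3
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise InvalidArgumentError("need 0 < f_min < f_max")
        if not (0 < self.alpha_phase < 1 and 0 < self.alpha_dominance < 1):
            raise InvalidArgumentError("significance levels must be in (0, 1)")


def load_config(path: PathLike) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    for key in ("probe_frequencies", "powerlaw_band"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: PathLike) -> None:
    data = dataclasses.asdict(config)
    data["probe_frequencies"] = list(config.probe_frequencies)
    data["powerlaw_band"] = list(config.powerlaw_band)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _read_table(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InvalidArgumentError(f"could not parse {path}: {exc}") from exc


def read_spikes(path: PathLike, duration: Optional[float] = None) -> Recording:
    """Read a spike file into a :class:`Recording`.

    Accepts CSV or TSV with columns ``unit_id, time_s, shank, depth_um``.
    Negative times are a parse error (with the offending line); unsorted
    times within a unit are sorted with a warning.
    """
    df = _read_table(path)
    required = {"unit_id", "time_s", "shank", "depth_um"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = np.flatnonzero(~np.isfinite(df["time_s"].to_numpy()) | (df["time_s"].to_numpy() < 0))
    if bad.size:
        raise InvalidArgumentError(
            f"{path}: invalid spike time at line {int(bad[0]) + 2}")
    total = float(duration) if duration is not None else float(df["time_s"].max()) * (1 + 1e-9)
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"unit {uid}: spike times unsorted, sorting")
            t = np.sort(t)
        units.append(SpikeTrain(t, duration=total, unit_id=str(uid),
                                shank=int(grp["shank"].iloc[0]),
                                depth_um=float(grp["depth_um"].iloc[0])))
    return Recording(units=units, duration=total)


def write_spikes(recording: Recording, path: PathLike, sep: str = "\t") -> None:
    frames = [
        pd.DataFrame({"unit_id": u.unit_id, "time_s": u.times,
                      "shank": u.shank, "depth_um": u.depth_um})
        for u in recording.units
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_signal(path: PathLike) -> ContinuousSignal:
    """Read a two-column ``time_s, value`` file; sampling must be uniform."""
    df = _read_table(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns time_s, value")
    t = df["time_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if t.size < 2:
        raise InvalidArgumentError(f"{path}: need >= 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6 * max(dt, 1.0)):
        raise InvalidArgumentError(f"{path}: sampling is not uniform")
    return ContinuousSignal(v, dt, t0=float(t[0]))


def write_signal(signal: ContinuousSignal, path: PathLike, sep: str = "\t") -> None:
    pd.DataFrame({"time_s": signal.times, "value": signal.values}).to_csv(
        path, sep=sep, index=False)


def write_results(table: pd.DataFrame, summary: dict, out_dir: PathLike,
                  stem: str = "results") -> Tuple[Path, Path]:
    """Write the per-unit result table (CSV) and the JSON summary sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    json_path = out / f"{stem}.json"
    table.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return csv_path, json_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
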