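"""End-to-end orchestration: per-unit spectra, power-law fits, coherence
and phase versus population rate and pupil, Fano factors and QC, collected
into one table per recording."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core import ContinuousSignal, Recording
from .spectral import (
    SegmentationPlan,
    TaperParams,
    fit_power_law,
    make_segmentation_plan,
    population_rate,
    spiketrain_psd,
)
from .coherence import coherency_spectrum, rate_adjust, _probe_index
from .phase import phase_spectrum, phase_distribution_summary
from .fano import default_bin_grid, fano_factor
from .timedomain import refractory_contamination
from .io import AnalysisConfig
from .synthetic import generate_population

__all__ = ["PipelineResult", "run_pipeline", "feasible_f_min"]

log = logging.getLogger("spikespectra.pipeline")


def feasible_f_min(duration: float, requested: float) -> float:
    """Lowest band edge reachable with >= 2 segments for this duration.

    The deepest band's top edge can sit just above ``f_min``, so its
    segment length approaches ``10 / f_min``; two segments then require
    ``f_min >= 20 / duration``.
    """
    return max(requested, 20.000001 / duration)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    summary: Dict
    errors: Dict[str, str] = field(default_factory=dict)


def _probe_plan(duration: float, freqs, f_max: float) -> SegmentationPlan:
    f_min = feasible_f_min(duration, min(freqs) * 0.74)
    return make_segmentation_plan(duration, f_min=f_min, f_max=f_max)


def run_pipeline(config: AnalysisConfig, recording: Optional[Recording] = None
                 ) -> PipelineResult:
    """Run the standard analysis over a recording (or the default synthetic
    scene when none is given).

    Per unit: power-law exponent beta of the spike-train PSD over the
    infraslow band (full recording and split halves), rate-adjusted
    coherence and phase with the population rate at the probe frequencies,
    coherence/phase with the pupil at 0.03 Hz (when a pupil signal exists),
    and the refractory-contamination QC metric.  Stage failures are
    isolated per unit and reported, not fatal.
    """
    if recording is None:
        recording = generate_population(
            n_neurons=config.n_neurons, duration=config.duration,
            antiphase_fraction=config.antiphase_fraction, seed=config.seed)
    taper = TaperParams(nw=config.taper_nw, k=config.taper_k)
    duration = recording.duration
    beta_lo = feasible_f_min(duration, config.powerlaw_band[0])
    beta_plan = make_segmentation_plan(duration, beta_lo, config.powerlaw_band[1])
    half = duration / 2.0
    half_lo = feasible_f_min(half, config.powerlaw_band[0])
    half_plan = make_segmentation_plan(half, half_lo, config.powerlaw_band[1])
    probe_plan = _probe_plan(duration, config.probe_frequencies, config.f_max)
    slow_f, fast_f = config.pupil_frequency, config.fast_frequency

    rows: List[dict] = []
    errors: Dict[str, str] = {}
    for i, unit in enumerate(recording.units):
        t0 = time.perf_counter()
        row: dict = {"unit_id": unit.unit_id, "shank": unit.shank,
                     "depth_um": unit.depth_um, "rate": unit.rate}
        try:
            snn = spiketrain_psd(unit, beta_plan, taper)
            row["beta"] = fit_power_law(snn, config.powerlaw_band).beta
            halves = [unit.restricted(0, half), unit.restricted(half, duration)]
            row["beta_half1"], row["beta_half2"] = (
                fit_power_law(spiketrain_psd(h, half_plan, taper),
                              (half_lo, config.powerlaw_band[1])).beta
                for h in halves)

            pop = population_rate(recording, i, bin=1e-3,
                                  exclusion_um=config.exclusion_um)
            est = coherency_spectrum(unit, pop, probe_plan, taper,
                                     alpha=config.alpha_phase)
            snn_probe = spiketrain_psd(unit, probe_plan, taper)
            adj = rate_adjust(est, snn_probe)
            ps = phase_spectrum(unit, pop, probe_plan, taper,
                                alpha=config.alpha_phase)
            for f0 in config.probe_frequencies:
                try:
                    j = _probe_index(est.frequencies, f0)
                except Exception:
                    continue
                row[f"coh_{f0:g}Hz"] = adj.rate_adjusted[j]
                row[f"coh_sig_{f0:g}Hz"] = bool(est.significant[j])
                row[f"phase_{f0:g}Hz"] = (ps.phase[j] if ps.defined[j] else np.nan)

            if recording.pupil is not None:
                pupil = recording.pupil
                p_plan = _probe_plan(duration, [slow_f], slow_f / 0.74)
                pest = coherency_spectrum(unit, pupil, p_plan, taper,
                                          alpha=config.alpha_phase)
                p_snn = spiketrain_psd(unit, p_plan, taper)
                padj = rate_adjust(pest, p_snn)
                pps = phase_spectrum(unit, pupil, p_plan, taper,
                                     alpha=config.alpha_phase)
                j = _probe_index(pest.frequencies, slow_f)
                row["pupil_coh"] = padj.rate_adjusted[j]
                row["pupil_phase"] = pps.phase[j] if pps.defined[j] else np.nan

            bins = default_bin_grid(config.n_fano_bins)
            bins = bins[bins <= duration / 10]
            fc = fano_factor(unit, bins)
            row["fano_1s"] = fc.fano[np.argmin(np.abs(np.log(bins)))]
            row["qc_contamination"] = refractory_contamination(unit)
        except Exception as exc:
            errors[unit.unit_id] = f"{type(exc).__name__}: {exc}"
            log.warning("unit %s failed: %s", unit.unit_id, exc)
        row["elapsed_s"] = time.perf_counter() - t0
        log.info("unit %s done in %.1f s", unit.unit_id, row["elapsed_s"])
        rows.append(row)

    table = pd.DataFrame(rows)
    summary = _summarise(table, recording, config)
    return PipelineResult(table, summary, errors)


def _summarise(table: pd.DataFrame, recording: Recording,
               config: AnalysisConfig) -> Dict:
    summary: Dict = {
        "n_units": len(recording.units),
        "duration_s": recording.duration,
        "seed": config.seed,
    }
    if "beta" in table:
        summary["beta_mean"] = float(np.nanmean(table["beta"]))
        summary["beta_sd"] = float(np.nanstd(table["beta"]))
    if {"beta_half1", "beta_half2"}.issubset(table.columns):
        ok = table[["beta_half1", "beta_half2"]].dropna()
        if len(ok) >= 3:
            r = np.corrcoef(ok["beta_half1"], ok["beta_half2"])[0, 1]
            summary["beta_split_half_r2"] = float(r**2)
    pcol = f"phase_{config.pupil_frequency:g}Hz"
    if pcol in table:
        phases = table[pcol].dropna().to_numpy()
        if phases.size >= 10:
            s = phase_distribution_summary(phases)
            summary["near_pi_fraction_slow"] = s.near_pi
    fcol = f"phase_{config.fast_frequency:g}Hz"
    if fcol in table:
        phases = table[fcol].dropna().to_numpy()
        if phases.size >= 10:
            summary["near_pi_fraction_fast"] = phase_distribution_summary(phases).near_pi
    # beta vs pupil coherence, split by pupil-phase group
    if {"pupil_coh", "pupil_phase", "beta"}.issubset(table.columns):
        ok = table[["pupil_coh", "pupil_phase", "beta"]].dropna()
        in_phase = ok[np.abs(ok["pupil_phase"]) <= np.pi / 2]
        anti = ok[np.abs(ok["pupil_phase"]) > np.pi / 2]
        for name, grp in (("in_phase", in_phase), ("antiphase", anti)):
            if len(grp) >= 5:
                rho, p = sp_stats.spearmanr(grp["beta"], grp["pupil_coh"])
                summary[f"beta_pupilcoh_spearman_{name}"] = float(rho)
                summary[f"beta_pupilcoh_p_{name}"] = float(p)
    return summary
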