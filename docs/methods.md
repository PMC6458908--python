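# Methods

This note records the models, estimators, numerical choices and known
limitations of `spikespectra`, in the package's own terms.

## Spectral estimation

**Model.** A spike train is treated as a doubly-stochastic (Cox) point
process: Poisson spiking with a random rate intensity λ(t).  Its power
spectrum decomposes as `S_nn(f) ≈ μ + S_λλ(f)` — a white floor at the mean
rate μ plus the intensity spectrum.  All spectra in the package are
**two-sided densities reported on the positive axis**: the variance of a
continuous signal is `2∫₀^∞ S df`, and a homogeneous Poisson train has the
flat level μ.  This is the convention under which the decomposition holds
with no stray factors of two.

**Segmentation.** Estimating 0.01–100 Hz from one recording needs
frequency-dependent time resolution.  A band just below a top edge `f_hi`
is estimated from non-overlapping segments of length `l = 10/f_hi`, using
the Fourier components `8/l, 9/l, 10/l`; the next band starts at
`f_hi' = 0.75·f_hi`, so bands tile the axis without gaps (three analysis
frequencies per band, ~33 bands over four decades).  For a 7200 s
recording this yields 72 000 segments of 0.1 s for 75–100 Hz down to 12
segments of 560 s for 0.0134–0.0179 Hz.  Frequencies below the segmented
range can be estimated from the whole recording in a single segment
(`whole_recording_psd`); that estimate has only 2K degrees of freedom and
is kept separate from the segmented analysis.

**Tapers and CIs.** Each segment is mean-subtracted and multitapered
(DPSS, time–bandwidth NW = 3, K = 5 tapers, unit-energy normalised).
Averaging M segments gives ν = 2KM degrees of freedom per frequency;
confidence intervals are asymptotic chi-squared intervals `S·ν/χ²_ν`.

**Binning.** Spikes are counted on a uniform grid per segment: 1 ms for
segments up to ~1 s, and a 1024-sample grid for longer ones.  Binning a
point process at any width leaves the white μ floor exact (the aliased
`sinc²` transfer sums to one), and each band only uses its lowest 8–10
Fourier components, far below the grid Nyquist, so the coarser infraslow
grids change nothing except cost.  Continuous signals are
integrate-and-averaged onto the band grid when they are finer than it;
when a signal is as coarse as (or coarser than) the band grid, segments
are cut on the signal's own grid instead, because piecewise-constant
upsampling would attenuate power near the signal's Nyquist.  Continuous
signals should in general be sampled a few times faster than the highest
band analysed against them.

**Power-law fits.** `fit_power_law` is an ordinary least-squares fit of
log power versus log frequency over 0.01–1 Hz (β = −slope).  By default it
fits `S_nn` itself, matching how spike-train exponents are usually
reported; `mode="excess"` fits `max(S_nn − μ, 10⁻⁶μ)` instead, targeting
`S_λλ`.  The μ floor biases the default mode downward when
`S_λλ(1 Hz) ≲ μ`, which is why parameter-recovery checks use the excess
mode.

**Population rate.** The summed spike rate of all units excluding the
target unit's shank (multi-shank probes) or all sites within 60 µm of the
target (single-shank probes), binned at 1 ms and treated as a continuous
signal throughout.

## Surrogate spike-train model

The generative model produces trains matching a target ISI histogram `I`
(32 log-spaced bins, 1 ms–200 s; out-of-range ISIs are clamped into the
terminal bins; within-bin sampling is log-uniform) and a target intensity
spectrum `℘` (the spectrum of the observed train convolved with a 50 ms
FWHM Gaussian, summarised at 50 log-spaced frequencies from
max(1/T, 0.005) Hz to 10 Hz; the white μ floor passes through the kernel,
so `℘ ≈ (μ + S_λλ)|G|²`).  `IntensityPSD` also records the mean rate — the
PSD-only mode needs it to build its implicit ISI law.

Pipeline: (1) sample a renewal train from `I` and smooth it → r₁(t);
(2) build r(t) with spectrum `℘` and **exactly** the value multiset of
r₁(t); (3) sample an inhomogeneous Poisson train n₁ from r(t) on a 10 ms
grid; (4) draw fresh ISIs from `I` and arrange them so the ISI rank
sequences of the output and of n₁ match exactly (ties broken by position,
stable).  The PSD-only mode substitutes an exponential ISI law with a hard
2 ms refractory period (its `support_min` truncates within-bin sampling so
the refractory bound is never violated); the ISI-only mode stops after
step 1.

**Spectrum/value matcher.** The iterative matcher alternates
Fourier-magnitude imposition with rank-remapping onto the donor's sorted
values, ending on a value step (value equality is therefore exact).  Two
numerical choices matter:

* *Compensated imposition.* Plain magnitude replacement stalls: the value
  step partially re-whitens the signal, leaving a severalfold low-frequency
  deficit.  The imposed amplitudes are therefore re-weighted each iteration
  by the measured-versus-target binned log-power mismatch (clipped to ±2);
  the residual — relative L2 distance of log power on the 50-point grid —
  typically reaches the 0.01 tolerance within ten iterations.
* *Extrapolation outside the grid.* Below the 0.005 Hz grid floor the
  imposed spectrum continues the power-law rise with the slope of the
  lowest grid bins (capped at flat): most of the power relevant to
  minute-bin spike-count dispersion lies below the grid floor, and flat
  extrapolation would suppress it.  Above 10 Hz the donor's own amplitudes
  are kept (same smoothing kernel, hence the correct rolloff).

The matcher starts from the donor itself, so a donor that already has the
target spectrum is a fixed point and the whole procedure is deterministic.
Because the value multiset pins the total variance, an exact spectral
match can be impossible; the iteration then stops when the residual stalls
(five iterations without 0.1% improvement) and flags non-convergence.

**Exactness caveat.** Spike times are stored as absolute times, so ISI
multisets pass through a cumsum→diff round trip; "exact" preservation
(shuffling, rank rearrangement) holds to float64 accumulation error,
about 10⁻⁹ s over a half-hour train.

## Fano factors and model scoring

Spike counts in non-overlapping bins (18 log-spaced sizes, 1 ms–100 s by
default; trailing partial bin discarded); FF = variance/mean (ddof = 1).
95% CIs are percentile bootstrap over bins (1000 resamples) up to 2000
bins, and a delta-method normal approximation beyond (the two coincide in
that regime).  Model error is `100·|obs − pred|/pred` per bin — the
convention under which a model that misses tenfold scores ~1000% — with
the observed-denominator variant available via an argument.

## Coherence and phase

Cross-spectra use the same segmentation, tapering and (per-band) grids as
the auto-spectra.  Coherence CIs use the Fisher transform with
SE = (ν−2)^(−1/2); the per-frequency significance threshold for zero
coherence is `√(1 − α^(1/(ν/2−1)))`.  The rate adjustment multiplies the
magnitude (and its CI) by `(1 + (μ−1)μ/S_nn)^(−1/2)`, clipping to [0, 1]
with a flag — for μ < 1 the correction is a boost and can clip under
estimation noise at low `S_nn`.

Pairwise dominance compares rate-adjusted coherences at the nine probe
frequencies 0.01–100 Hz with one-sided Z-tests on Fisher-transformed
magnitudes, Bonferroni-corrected across probes at α = 0.001; "crossed"
means each unit is significantly stronger somewhere.

Phase is the argument of the cross-spectrum of the unit against the
signal, so a positive phase means the unit leads; a unit following the
signal with a pure delay Δt shows phase −2πfΔt.  Per frequency, the
per-segment phases are pooled; the circular mean and SD are reported only
where a Rayleigh test rejects uniformity at P ≤ 0.05.  The
linearity/logarithmicity indices are natural-log ratios of the phase-set
diameters on the upper versus lower half of the longest well-defined
interval (split at the arithmetic or geometric mean of its endpoints);
diameters are circular (smallest covering arc) so curves crossing ±π are
handled; intervals spanning under a decade are excluded, and ties between
runs are broken by log-frequency width.  The circular explained variance
of a phase model is `1 − (1−R̄_resid)/(1−R̄_total)` with R̄ the mean
resultant lengths of the residual and raw phase distributions.

## Time-domain coupling and QC

The coupling curve is the lagged inner product of the population rate with
the unit's spike train divided by the unit's spike count: at 1 ms
resolution with the unit smoothed by a Gaussian of 12 ms half-width at
half-maximum (lags ±1 s, baseline from 0.8–1 s), or at 1 s resolution
(lags ±20 s, baseline 12–20 s).  Refractory contamination is the mean
autocorrelogram density in (0, 2 ms] over the density in a 50–100 ms
asymptote window; the unit-quality screen is < 0.2.

## Synthetic data

Each neuron's log intensity is a weighted sum of band-limited power-law
latents passed through an exponential link and renormalised so the time
average equals the target rate exactly (hence proportional intensities
across rates, the property the rate adjustment is tested against).
Latents are built by Fourier-domain shaping (amplitudes ∝ f^(−β/2) inside
the band, zero outside, random phases), with the sample variance
normalised exactly.  Defaults:

* latent bands extend from 10⁻⁴ Hz (effectively the recording length) to
  0.5–1 Hz: cortical rate fluctuations are scale-free down to the
  recording length, and power below ~0.008 Hz is what drives minute-bin
  Fano factors;
* the default scene: 40 neurons, 7200 s, 1 ms intensity grid, lognormal
  rates (median 4 spikes/s, clipped to 0.5–20), shared slow latent
  (β = 0.4) with couplings U(0.4, 0.8) and 30% of neurons antiphase,
  shared fast latent (flat, 1–30 Hz) with couplings U(0.1, 0.3), private
  per-neuron latents with β ~ U(0.2, 0.6), per-neuron leads/lags of the
  arousal latent (N(0, 3 s), giving the ~0.6 rad within-mode spread of
  infraslow phase preferences that recorded populations show), and a 2 ms
  dead time imposed by deleting spikes too close to the previous accepted
  spike;
* the independent-neuron cohort for single-train analyses: log-uniform
  rates on [1, 10] spikes/s and private coupling weights U(0.6, 1.2),
  calibrated so the cohort's observed/ISI-shuffled Fano ratios at 1.024 s
  and 16.384 s bins (~1.9 and ~3.6) sit close to the severalfold values
  that motivate the joint surrogate model;
* the pupil surrogate is the slow latent low-passed (second-order
  Butterworth at 0.2 Hz, zero-phase) and delayed by 4.14 s, so spiking
  leads the pupil by 2π·0.03·4.14 ≈ 0.78 rad at 0.03 Hz; sampled at 10 Hz.

What the generator does **not** emulate: spike-sorting artefacts and probe
drift, bursting and other non-Poisson fast structure beyond the hard dead
time, non-stationary arousal statistics (the latents are stationary
Gaussian before the link), and cell-type heterogeneity beyond the
parameter ranges above.  Tests passing on this data therefore validate the
estimators and the pipeline plumbing, not the neuroscience of any real
recording.

## Problem sizes and determinism

Every generator and estimator is a pure function of its inputs and an
integer seed (child seeds spawned via `numpy` `SeedSequence`).  The test
suite and the acceptance script use: a 40-neuron, 2 h default scene; a
20-neuron, 2 h cohort for the surrogate-model comparison (Fano scored at
the 65 s bin); three rates (1, 5, 20 spikes/s) over 2 h for the coherence
identity; 10 neurons per exponent for power-law recovery; 2 h of
homogeneous Poisson at 5 spikes/s for calibration.  Module unit tests use
minutes-long toys.

## Known limitations

* Analysis frequencies within a band are labelled `j/l`; in the
  coarse-signal (sliced) layout the effective segment length differs from
  `l` by up to half a native sample, a sub-bandwidth relabelling.
* The surrogate model inherits the μ|G|² noise floor inside `℘`, so its
  intensity slightly over-disperses when μ is comparable to the infraslow
  `S_λλ`; with realistic modulation depths the bias is well below the
  single-realization noise of minute-bin Fano factors.
* Coherence CIs are asymptotic; for the deepest band (M ≈ 7–12 segments)
  they are approximate and the acceptance checks require only 80%
  CI coverage there.
* The pairwise-dominance test treats the nine probe frequencies as
  independent (Bonferroni), which is conservative.
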