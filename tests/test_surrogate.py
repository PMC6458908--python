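"""Surrogate spike-train model: ISI histogram, intensity-PSD target, the
spectrum/value matcher, rank rearrangement and the three model modes."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import poisson_train
from spikespectra.core import ContinuousSignal, EmptyInputError, InvalidArgumentError, SpikeTrain
from spikespectra.spectral import continuous_psd, fit_power_law, make_segmentation_plan
from spikespectra.surrogate import (
    ISIDistribution,
    IntensityPSD,
    SMOOTHING_FWHM,
    _isi_edges,
    _smooth_rate,
    exponential_isi,
    intensity_psd_target,
    isi_histogram,
    isi_shuffle,
    match_spectrum_and_values,
    rank_rearrange,
    sample_isi_train,
    synthesize,
)
from spikespectra.synthetic import generate_independent_neurons


@pytest.fixture(scope="module")
def modulated_neuron():
    """One strongly rate-modulated doubly-stochastic neuron (30 min)."""
    return generate_independent_neurons(
        n_neurons=1, duration=1800.0, beta=0.4, rate_range=(5.0, 5.0),
        coupling_range=(1.0, 1.0), seed=3)[0][0]


class TestISIHistogram:
    def test_regular_train_occupies_a_single_bin(self):
        st = SpikeTrain(np.arange(1000) * 0.01, duration=10.0)
        h = isi_histogram(st)
        assert h.probabilities.max() == pytest.approx(1.0)
        i = np.argmax(h.probabilities)
        assert h.bin_edges[i] <= 0.01 <= h.bin_edges[i + 1]

    def test_exponential_isis_match_analytic_bin_masses(self):
        rate, n = 5.0, 100_000
        rng = np.random.default_rng(17)
        isis = rng.exponential(1.0 / rate, n)
        st = SpikeTrain(np.concatenate([[0.0], np.cumsum(isis)]),
                        duration=float(np.sum(isis)) * 1.001)
        h = isi_histogram(st)
        edges = h.bin_edges
        analytic = np.diff(1.0 - np.exp(-rate * edges))
        analytic[0] += 1.0 - math.exp(-rate * edges[0])  # sub-1 ms mass clamps in
        analytic[-1] += math.exp(-rate * edges[-1])
        sd = np.sqrt(analytic * (1 - analytic) / n)
        assert np.all(np.abs(h.probabilities - analytic) <= 4 * sd + 1e-12)

    def test_out_of_range_isis_clamped_into_terminal_bins(self):
        st = SpikeTrain(np.array([0.0, 1e-4, 300.0]), duration=400.0)
        h = isi_histogram(st)
        assert h.probabilities[0] == pytest.approx(0.5)
        assert h.probabilities[-1] == pytest.approx(0.5)

    def test_single_spike_rejected(self):
        with pytest.raises(EmptyInputError):
            isi_histogram(SpikeTrain(np.array([1.0]), duration=2.0))


class TestIntensityPSDTarget:
    def test_poisson_target_matches_filtered_white_spectrum(self):
        # smoothed homogeneous Poisson: S(f) = mu * |G(f)|^2 with G the
        # 50 ms FWHM Gaussian transfer
        mu, duration = 5.0, 3600.0
        sigma = SMOOTHING_FWHM / (2 * math.sqrt(2 * math.log(2)))
        acc = None
        for s in range(10):
            p = intensity_psd_target(poisson_train(mu, duration, seed=100 + s))
            acc = p.power if acc is None else acc + p.power
        acc /= 10
        analytic = mu * np.exp(-((2 * np.pi * p.frequencies * sigma) ** 2))
        rel = acc / analytic - 1
        assert np.linalg.norm(rel) / np.sqrt(rel.size) < 0.15
        assert np.max(np.abs(rel)) < 0.5  # lowest bins average few Fourier points

    def test_grid_has_exactly_50_entries(self):
        p = intensity_psd_target(poisson_train(5.0, 1800.0, seed=1))
        assert p.frequencies.size == 50 and p.power.size == 50

    def test_slow_sinusoidal_intensity_elevates_the_nearest_grid_point(self):
        duration, dt = 3600.0, 0.01
        t = np.arange(int(duration / dt)) * dt
        lam = ContinuousSignal(5.0 * (1 + 0.8 * np.sin(2 * np.pi * 0.03 * t)), dt)
        from spikespectra.synthetic import sample_spike_train
        st = sample_spike_train(lam, seed=7)
        p = intensity_psd_target(st)
        i = np.argmin(np.abs(np.log(p.frequencies / 0.03)))
        others = np.delete(p.power, [i - 1, i, i + 1])
        assert p.power[i] > 5 * np.median(others)

    def test_too_short_recording_rejected(self):
        with pytest.raises(Exception):
            intensity_psd_target(poisson_train(50.0, 200.0, seed=2))


class TestSampleISITrain:
    def test_single_bin_distribution_gives_near_regular_train(self):
        edges = _isi_edges()
        probs = np.zeros(32)
        i = np.searchsorted(edges, 0.01) - 1
        probs[i] = 1.0
        isi = ISIDistribution(edges, probs)
        st = sample_isi_train(isi, 100.0, seed=5)
        # the law's mean ISI sits near 10 ms (log-uniform within the bin)
        assert st.rate == pytest.approx(1.0 / isi.mean_isi, rel=0.05)
        assert st.rate == pytest.approx(100.0, rel=0.25)
        assert edges[i] <= st.isis.min() * (1 + 1e-9)
        assert st.isis.max() <= edges[i + 1] * (1 + 1e-9)

    def test_output_histogram_reproduces_the_law(self, modulated_neuron):
        target = isi_histogram(modulated_neuron)
        st = sample_isi_train(target, 1800.0, seed=6)
        out = isi_histogram(st)
        n = st.isis.size
        sd = np.sqrt(target.probabilities * (1 - target.probabilities) / n)
        assert np.all(np.abs(out.probabilities - target.probabilities)
                      <= 5 * sd + 3.0 / n)

    def test_renewal_resample_loses_infraslow_power(self, modulated_neuron):
        # i.i.d. ISI draws destroy the slow rate fluctuations: the smoothed
        # renewal train has several-fold less sub-0.1 Hz power
        target = isi_histogram(modulated_neuron)
        renewal = sample_isi_train(target, 1800.0, seed=8)
        plan = make_segmentation_plan(1800.0, 0.012, 0.1)
        p_obs = continuous_psd(_smooth_rate(modulated_neuron), plan)
        p_ren = continuous_psd(_smooth_rate(renewal), plan)
        assert np.mean(p_obs.power) > 3 * np.mean(p_ren.power)


class TestMatcher:
    def test_donor_with_target_spectrum_is_a_fixed_point(self):
        st = poisson_train(5.0, 1800.0, seed=9)
        target = intensity_psd_target(st)
        donor = _smooth_rate(st)
        out = match_spectrum_and_values(target, donor)
        assert out.meta["iterations"] <= 2
        assert out.meta["residual"] <= 0.02
        np.testing.assert_array_equal(np.sort(out.values), np.sort(donor.values))

    def test_value_multiset_is_always_exactly_preserved(self):
        rng = np.random.default_rng(10)
        donor = ContinuousSignal(rng.gamma(2.0, 2.0, 180_000), 0.01)
        f = np.geomspace(0.005, 10.0, 50)
        target = IntensityPSD(f, 5.0 / f**0.4, mean_rate=4.0)
        out = match_spectrum_and_values(target, donor)
        np.testing.assert_array_equal(np.sort(out.values), np.sort(donor.values))

    def test_flat_donor_acquires_powerlaw_spectrum(self):
        rng = np.random.default_rng(11)
        duration = 3600.0
        donor = ContinuousSignal(rng.gamma(4.0, 1.0, int(duration / 0.01)), 0.01)
        f = np.geomspace(0.005, 10.0, 50)
        # normalise the target so its integral is near the donor variance
        shape = 1.0 / f**0.4
        shape *= donor.values.var() / (2 * np.trapezoid(shape, f))
        target = IntensityPSD(f, shape, mean_rate=float(donor.values.mean()))
        out = match_spectrum_and_values(target, donor)
        plan = make_segmentation_plan(duration, 0.012, 1.0)
        fit = fit_power_law(continuous_psd(out, plan), (0.012, 1.0))
        assert fit.beta == pytest.approx(0.4, abs=0.15)

    def test_negative_donor_rejected(self):
        donor = ContinuousSignal(np.array([1.0, -0.5] * 50), 0.01)
        f = np.geomspace(0.01, 10, 50)
        with pytest.raises(InvalidArgumentError):
            match_spectrum_and_values(IntensityPSD(f, np.ones(50), 1.0), donor)


class TestRankRearrange:
    def test_monotone_template_yields_monotone_output(self):
        times = np.concatenate([[0.0], np.cumsum(np.linspace(0.01, 1.0, 60))])
        template = SpikeTrain(times, duration=float(times[-1]) + 1)
        isi = exponential_isi(5.0)
        out = rank_rearrange(template, isi, seed=12)
        assert np.all(np.diff(out.isis) >= 0)

    def test_rank_sequences_match_exactly(self, modulated_neuron):
        isi = isi_histogram(modulated_neuron)
        out = rank_rearrange(modulated_neuron, isi, seed=13)
        r_t = np.argsort(np.argsort(modulated_neuron.isis, kind="stable"), kind="stable")
        r_o = np.argsort(np.argsort(out.isis, kind="stable"), kind="stable")
        np.testing.assert_array_equal(r_t, r_o)

    def test_output_isis_are_iid_draws_from_the_law(self):
        # KS against the analytic CDF of the binned law (log-uniform within
        # bins) stays below the 5% critical value in >= 95% of seeds
        isi = exponential_isi(5.0, refractory=0.0)
        edges, probs = isi.bin_edges, isi.probabilities
        cum = np.concatenate([[0.0], np.cumsum(probs)])

        def cdf(x):
            x = np.clip(x, edges[0], edges[-1])
            i = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 31)
            frac = np.log(x / edges[i]) / np.log(edges[i + 1] / edges[i])
            return cum[i] + probs[i] * frac

        template = poisson_train(5.0, 100.0, seed=0)
        rejections = 0
        for s in range(100):
            out = rank_rearrange(template, isi, seed=1000 + s)
            rejections += stats.kstest(out.isis, cdf).pvalue <= 0.05
        # nominal 5% rejection rate, plus 3 binomial SDs of slack
        assert rejections <= 100 * (0.05 + 3 * math.sqrt(0.05 * 0.95 / 100))


class TestSynthesizeModes:
    def test_full_mode_reproduces_the_fano_curve(self, cohort):
        # millisecond-to-half-minute bins: within 25% pointwise; at minute
        # bins a 2 h recording leaves < 120 count samples and the Fano
        # estimates' own 95% CIs exceed 25%, so there the check is CI overlap
        from spikespectra.fano import default_bin_grid, fano_factor
        obs, _ = cohort[0]
        res = synthesize(isi=isi_histogram(obs), psd=intensity_psd_target(obs),
                         duration=obs.duration, seed=0)
        bins = default_bin_grid()
        fo = fano_factor(obs, bins)
        fp = fano_factor(res.spikes, bins)
        rel = np.abs(fp.fano - fo.fano) / fo.fano
        tight = bins <= 32.0
        assert np.all(rel[tight] < 0.25)
        loose = ~tight
        overlap = (fp.ci_low[loose] <= fo.ci_high[loose]) & \
                  (fo.ci_low[loose] <= fp.ci_high[loose])
        assert np.all(overlap)

    def test_full_mode_matches_isi_histogram_and_spectrum(self, modulated_neuron):
        isi = isi_histogram(modulated_neuron)
        psd = intensity_psd_target(modulated_neuron)
        res = synthesize(isi=isi, psd=psd, duration=1800.0, seed=14)
        out_h = isi_histogram(res.spikes)
        n = res.spikes.isis.size
        sd = np.sqrt(isi.probabilities * (1 - isi.probabilities) / n)
        assert np.all(np.abs(out_h.probabilities - isi.probabilities)
                      <= 5 * sd + 3.0 / n)
        assert res.spectrum_discrepancy <= 0.1
        # rank identity between the output and the intermediate train
        r_n1 = np.argsort(np.argsort(res.intermediate.isis, kind="stable"), kind="stable")
        r_n = np.argsort(np.argsort(res.spikes.isis, kind="stable"), kind="stable")
        np.testing.assert_array_equal(r_n1, r_n)

    def test_psd_only_mode_never_violates_the_refractory_period(self, modulated_neuron):
        res = synthesize(psd=intensity_psd_target(modulated_neuron),
                         duration=1800.0, seed=15)
        assert res.mode == "psd_only"
        assert res.spikes.isis.min() >= 2e-3

    def test_isi_only_mode_underpredicts_slow_dispersion(self, modulated_neuron):
        from spikespectra.fano import fano_factor
        bins = np.array([16.384])
        res = synthesize(isi=isi_histogram(modulated_neuron),
                         duration=1800.0, seed=16)
        ff_obs = fano_factor(modulated_neuron, bins).fano[0]
        ff_isi = fano_factor(res.spikes, bins).fano[0]
        assert ff_obs > 2.5 * ff_isi

    def test_both_inputs_absent_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize(duration=100.0, seed=0)

    def test_deterministic_given_seed(self, modulated_neuron):
        isi = isi_histogram(modulated_neuron)
        a = synthesize(isi=isi, duration=600.0, seed=17)
        b = synthesize(isi=isi, duration=600.0, seed=17)
        assert np.array_equal(a.spikes.times, b.spikes.times)


class TestISIShuffle:
    def test_multiset_and_count_preserved(self, modulated_neuron):
        # exact up to the float64 accumulation error of rebuilding absolute
        # spike times from the permuted intervals (~1e-9 s over 30 min)
        out = isi_shuffle(modulated_neuron, seed=18)
        assert out.n_spikes == modulated_neuron.n_spikes
        np.testing.assert_allclose(np.sort(out.isis),
                                   np.sort(modulated_neuron.isis),
                                   rtol=1e-6, atol=1e-8)
        assert out.times[0] == modulated_neuron.times[0]

    def test_shuffling_removes_infraslow_power(self, modulated_neuron):
        plan = make_segmentation_plan(1800.0, 0.012, 0.1)
        p_obs = continuous_psd(_smooth_rate(modulated_neuron), plan)
        p_sh = continuous_psd(_smooth_rate(isi_shuffle(modulated_neuron, seed=19)), plan)
        assert np.mean(p_obs.power) > 3 * np.mean(p_sh.power)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(EmptyInputError):
            isi_shuffle(SpikeTrain(np.array([0.1, 0.2]), 1.0))


def test_exponential_isi_law_respects_mean_and_refractory():
    law = exponential_isi(4.0, refractory=2e-3)
    assert law.support_min == 2e-3
    assert law.mean_isi == pytest.approx(0.25, rel=0.05)
    assert law.probabilities.sum() == pytest.approx(1.0)
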