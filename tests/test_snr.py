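"""SNR estimators, scaling-law fits and the acquisition-time calculator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import scene_for
from dcpas.interferogram import Interferogram, coherent_average, remove_acoustic_delay, simulate_shot
from dcpas.processing import Spectrum
from dcpas.snr import (
    ScalingScenario,
    SNRResult,
    acquisition_time_scale,
    apodization_snr_gain,
    fit_power_linear,
    fit_sqrt_tau,
    shots_to_reach_snr,
    spectral_snr,
    time_domain_snr,
)


class TestTimeDomainSnr:
    def test_peak_over_noise_std(self):
        samples = np.tile([0.1, -0.1], 200).astype(float)  # std exactly 0.1
        samples[0] = 1.0
        igm = Interferogram(samples, sample_rate=1e6)
        r = time_domain_snr(igm, centerburst_halfwidth=2e-6,
                            exclusion_halfwidth=10e-6)
        assert r.value == pytest.approx(10.0, rel=0.01)

    def test_noiseless_flags_infinity(self):
        samples = np.zeros(400)
        samples[0] = 1.0
        r = time_domain_snr(Interferogram(samples, 1e6),
                            centerburst_halfwidth=2e-6)
        assert r.infinite

    def test_averaging_time_is_shots_times_period(self):
        igm = Interferogram(np.ones(1000), sample_rate=1e6, n_averaged=8)
        r = time_domain_snr(igm, centerburst_halfwidth=2e-6)
        assert r.averaging_time == pytest.approx(8 * 1e-3)

    def test_exclusion_narrower_than_centerburst_rejected(self):
        igm = Interferogram(np.ones(100), sample_rate=1e6)
        with pytest.raises(ValueError):
            time_domain_snr(igm, centerburst_halfwidth=5e-6,
                            exclusion_halfwidth=1e-6)

    def test_weak_scene_reaches_snr32_after_1024_averages(self):
        """A scene with true single-shot SNR ~1 reads SNR ~32 after 1024 shots."""
        noise = 4.5e-2
        scene = scene_for("vacnt", "reduced", noise=noise, seed=5)
        clean = scene_for("vacnt", "reduced", seed=5)
        kw = dict(centerburst_halfwidth=0.5e-6, exclusion_halfwidth=1.5e-6)
        shots = [simulate_shot(scene, i)[1] for i in range(1024)]
        avg = remove_acoustic_delay(coherent_average(shots),
                                    scene.chain.t_acoustic)
        signal = remove_acoustic_delay(simulate_shot(clean, 0)[1],
                                       scene.chain.t_acoustic)
        # true single-shot SNR from the known signal and one noise realization
        resid = remove_acoustic_delay(shots[0], scene.chain.t_acoustic)
        sigma = np.std(resid.samples - signal.samples)
        true_single = np.max(np.abs(signal.samples)) / sigma
        assert true_single == pytest.approx(1.0, rel=0.2)  # tuned operating point
        snr1024 = time_domain_snr(avg, **kw).value
        assert snr1024 == pytest.approx(32.0 * true_single, rel=0.1)


class TestSpectralSnr:
    def _noise_spectra(self, n_rep, n_bins=2000, sigma=1.0, seed=0):
        rng = np.random.default_rng(seed)
        f = np.arange(1.0, n_bins + 1.0)
        return [Spectrum(f, np.abs(rng.normal(0, sigma, n_bins)))
                for _ in range(n_rep)]

    def test_requires_eight_repeats(self):
        with pytest.raises(ValueError):
            spectral_snr(self._noise_spectra(5))

    def test_identical_repeats_are_infinite(self):
        f = np.arange(1.0, 50.0)
        spec = Spectrum(f, np.ones(49))
        out = spectral_snr([spec] * 10)
        assert np.all(np.isinf(out))

    def test_pure_noise_matches_folded_normal_moments(self):
        # |N(0,s)|: mean/std = sqrt(2/pi) / sqrt(1 - 2/pi) = 1.3237
        out = spectral_snr(self._noise_spectra(100))
        expected = math.sqrt(2 / math.pi) / math.sqrt(1 - 2 / math.pi)
        assert np.mean(out) == pytest.approx(expected, rel=0.05)

    def test_strong_signal_estimates_s_over_sigma(self):
        rng = np.random.default_rng(3)
        f = np.arange(1.0, 301.0)
        reps = [Spectrum(f, 50.0 + rng.normal(0, 1.0, 300)) for _ in range(32)]
        out = spectral_snr(reps)
        assert np.median(out) == pytest.approx(50.0, rel=0.2)


class TestFits:
    def test_exact_sqrt_tau_points(self):
        pts = [SNRResult(3 * math.sqrt(t), averaging_time=t)
               for t in (0.1, 1.0, 3.0, 10.0)]
        fit = fit_sqrt_tau(pts)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-9)
        assert fit.exponent == pytest.approx(0.5, abs=1e-9)

    def test_coherent_drift_flagged_by_exponent(self):
        pts = [SNRResult(2 * t, averaging_time=t) for t in (0.1, 1.0, 3.0, 10.0)]
        assert fit_sqrt_tau(pts).exponent == pytest.approx(1.0, abs=1e-9)

    def test_sqrt_tau_input_validation(self):
        good = [SNRResult(1.0, averaging_time=t) for t in (1, 2, 4, 20)]
        with pytest.raises(ValueError):
            fit_sqrt_tau(good[:3])
        short = [SNRResult(1.0, averaging_time=t) for t in (1.0, 1.5, 2.0, 3.0)]
        with pytest.raises(ValueError):
            fit_sqrt_tau(short)
        bad = [SNRResult(-1.0, averaging_time=t) for t in (1, 2, 4, 20)]
        with pytest.raises(ValueError):
            fit_sqrt_tau(bad)

    def test_exact_linear_power_points(self):
        pts = [SNRResult(2.0 * p, power=p) for p in (1.0, 2.0, 3.0)]
        slope, intercept, exponent = fit_power_linear(pts)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert exponent == pytest.approx(1.0, abs=1e-9)

    def test_shot_noise_scaling_flagged(self):
        pts = [SNRResult(4 * math.sqrt(p), power=p) for p in (1.0, 4.0, 9.0)]
        _, _, exponent = fit_power_linear(pts)
        assert exponent == pytest.approx(0.5, abs=1e-9)

    def test_power_fit_degenerate(self):
        pts = [SNRResult(1.0, power=2.0)] * 3
        with pytest.raises(ValueError):
            fit_power_linear(pts)


class TestScalingCalculator:
    def test_discussion_projection(self):
        # 3000x repetition rate and 10x absorbance: 300,000-fold, 2 h -> 24 ms
        t, s, proj = acquisition_time_scale(
            ScalingScenario(f_rep_factor=3000, absorbance_factor=10,
                            baseline_time=7200.0)
        )
        assert 1.0 / t == pytest.approx(300000, rel=1e-9)
        assert proj == pytest.approx(0.024, rel=1e-9)

    def test_rep_rate_snr_gain(self):
        _, s, _ = acquisition_time_scale(ScalingScenario(f_rep_factor=3000))
        assert s == pytest.approx(math.sqrt(3000), rel=1e-9)
        assert round(s) == 55

    def test_identity(self):
        t, s, proj = acquisition_time_scale(ScalingScenario(baseline_time=42.0))
        assert (t, s, proj) == (1.0, 1.0, 42.0)

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=0.1, max_value=10),
        p=st.floats(min_value=0.1, max_value=10),
        q=st.floats(min_value=0.1, max_value=10),
    )
    @settings(deadline=None, max_examples=50)
    def test_multiplicative_composition(self, a, b, p, q):
        t1, _, _ = acquisition_time_scale(
            ScalingScenario(f_rep_factor=a, power_factor=p))
        t2, _, _ = acquisition_time_scale(
            ScalingScenario(f_rep_factor=b, power_factor=q))
        t12, _, _ = acquisition_time_scale(
            ScalingScenario(f_rep_factor=a * b, power_factor=p * q))
        assert t12 == pytest.approx(t1 * t2, rel=1e-9)

    def test_invalid_factors(self):
        with pytest.raises(ValueError):
            ScalingScenario(f_rep_factor=0.0)


class TestApodizationGain:
    def test_analytic_value(self):
        assert apodization_snr_gain(500e9, 160e6) == pytest.approx(
            math.sqrt(3125), rel=1e-12
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            apodization_snr_gain(100e6, 160e6)


class TestShotsToReachSnr:
    def test_stronger_signal_needs_fewer_shots(self):
        weak = scene_for("vacnt", "reduced", noise=1e-2,
                         sample__beta_Pa_per_W=0.25)
        strong = scene_for("vacnt", "reduced", noise=1e-2)
        kw = dict(centerburst_halfwidth=0.5e-6, exclusion_halfwidth=1.5e-6)
        m_weak = shots_to_reach_snr(weak, 20.0, seed=11, **kw)
        m_strong = shots_to_reach_snr(strong, 20.0, seed=11, **kw)
        # 4x the amplitude -> ~16x fewer shots
        assert m_weak / m_strong == pytest.approx(16.0, rel=0.5)

    def test_requires_noise_and_no_jitter(self, reduced_vacnt_scene):
        with pytest.raises(ValueError):
            shots_to_reach_snr(reduced_vacnt_scene, 10.0, seed=0)
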