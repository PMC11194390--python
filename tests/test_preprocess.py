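"""Preprocessing chain: segmentation, normalization, denoisers, quality."""

import numpy as np
import pytest

from pulsekfd.errors import DataError, DetectionError, ParameterError
from pulsekfd.preprocess import (
    PulseBeat,
    bandpass_denoise,
    estimate_residual_snr,
    extract_beats,
    gaussian_denoise,
    median_denoise,
    normalize_beat,
    segment_beats,
    sqi_screen,
)
from pulsekfd.estimation_eval import add_noise

from conftest import ADMISSIBLE_BEAT_PARAMS, make_admissible_beat

FS = 500.0


def _beat_train(n_beats=12, hr=1.0 / 0.82, fs=FS):
    _, beat = make_admissible_beat(ADMISSIBLE_BEAT_PARAMS[0], n=int(round(fs / hr)), fs=fs, hr=hr)
    return np.tile(beat.samples, n_beats), beat


class TestSegmentBeats:
    def test_periodic_train_period_recovered(self):
        sig, beat = _beat_train()
        sig = sig[: int(10 * FS)]  # 10 s
        intervals = segment_beats(sig, FS)
        assert 10 <= len(intervals) <= 13
        lengths = np.array([b - a for a, b in intervals])
        assert np.median(lengths) / FS == pytest.approx(0.82, abs=0.02)

    def test_tiled_cycle_gives_exact_multiples(self):
        sig, beat = _beat_train(n_beats=5)
        intervals = segment_beats(sig, FS)
        lengths = {b - a for a, b in intervals}
        assert lengths == {beat.n}

    def test_constant_signal_raises(self):
        with pytest.raises(DetectionError):
            segment_beats(np.ones(int(3 * FS)), FS)

    def test_short_signal_raises(self):
        with pytest.raises(DetectionError):
            segment_beats(np.sin(np.arange(100) / 10.0), FS)

    def test_extract_beats_sets_per_beat_heart_rate(self):
        sig, beat = _beat_train(n_beats=6)
        beats = extract_beats(sig, FS)
        for b in beats:
            assert b.HR == pytest.approx(FS / beat.n, rel=1e-9)
            assert b.delta_v is not None


class TestNormalizeBeat:
    def test_affine_rescale_and_delta_v(self):
        beat = PulseBeat(samples=np.linspace(2.0, 4.5, 100), fs=FS, HR=1.2)
        out = normalize_beat(beat)
        assert out.samples.min() == 0.0
        assert out.samples.max() == 1.0
        assert out.delta_v == pytest.approx(2.5)

    def test_idempotent_on_normalized_beat(self):
        beat = normalize_beat(PulseBeat(samples=np.linspace(0, 1, 50) ** 2, fs=FS, HR=1.2))
        again = normalize_beat(beat)
        np.testing.assert_allclose(again.samples, beat.samples, atol=1e-15)

    def test_gain_invariance(self):
        y = np.sin(np.linspace(0, np.pi, 80))
        a = normalize_beat(PulseBeat(samples=y, fs=FS, HR=1.2))
        b = normalize_beat(PulseBeat(samples=7.3 * y + 2.0, fs=FS, HR=1.2))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)

    def test_flat_beat_raises(self):
        with pytest.raises(DataError):
            normalize_beat(PulseBeat(samples=np.ones(50), fs=FS, HR=1.2))


class TestMedianDenoise:
    def test_isolated_spike_removed(self):
        y = np.sin(np.linspace(0, np.pi, 200))
        noisy = y.copy()
        noisy[100] += 10.0
        beat = PulseBeat(samples=noisy, fs=FS, HR=1.2)
        out = median_denoise(beat, window=15)
        assert abs(out.samples[100] - y[100]) < 0.01 * max(1.0, abs(y[100]))

    def test_monotone_ramp_fixed_point_away_from_edges(self):
        y = np.linspace(0.0, 1.0, 100)
        out = median_denoise(PulseBeat(samples=y, fs=FS, HR=1.2), window=15)
        np.testing.assert_allclose(out.samples[8:-8], y[8:-8], atol=1e-12)

    def test_window_one_is_identity(self):
        y = np.random.default_rng(0).normal(size=60)
        out = median_denoise(PulseBeat(samples=y, fs=FS, HR=1.2), window=1)
        np.testing.assert_array_equal(out.samples, y)

    @pytest.mark.parametrize("window", [4, 101])
    def test_bad_window_rejected(self, window):
        beat = PulseBeat(samples=np.sin(np.linspace(0, np.pi, 100)), fs=FS, HR=1.2)
        with pytest.raises(ParameterError):
            median_denoise(beat, window=window)


class TestBandpassDenoise:
    t = np.arange(0, 30, 1 / FS)

    def test_in_band_tone_preserved(self):
        y = bandpass_denoise(np.sin(2 * np.pi * 1.0 * self.t), FS)
        mid = slice(y.size // 4, 3 * y.size // 4)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("freq", [0.05, 50.0])
    def test_stopband_tones_suppressed(self, freq):
        y = bandpass_denoise(np.sin(2 * np.pi * freq * self.t), FS)
        mid = slice(y.size // 4, 3 * y.size // 4)
        assert np.max(np.abs(y[mid])) < 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_denoise(np.sin(self.t[:1000]), 60.0)


class TestGaussianDenoise:
    @pytest.mark.parametrize("params", ADMISSIBLE_BEAT_PARAMS)
    def test_exact_recovery_of_admissible_beats(self, params):
        from pulsekfd.preprocess import _theta_to_components

        theta, beat = make_admissible_beat(params)
        _, decomp = gaussian_denoise(beat)
        assert decomp.rmse < 1e-3
        a, c, w = _theta_to_components(theta)
        T = beat.n / beat.fs
        fit_a = np.array(list(decomp.amplitudes.values()))
        fit_c = np.array(list(decomp.centers.values())) / T
        fit_w = np.array(list(decomp.widths.values())) / T
        np.testing.assert_allclose(fit_a, a, rtol=0.02)
        np.testing.assert_allclose(fit_c, c, rtol=0.02)
        np.testing.assert_allclose(fit_w, w, rtol=0.02)

    def test_denoising_reduces_error_at_15db(self):
        _, clean = make_admissible_beat(ADMISSIBLE_BEAT_PARAMS[0])
        noisy_samples = add_noise(clean.samples, 15.0, seed=7)
        noisy_samples = np.clip(noisy_samples, -0.04, 1.14)
        noisy = PulseBeat(samples=noisy_samples, fs=clean.fs, HR=clean.HR)
        denoised, _ = gaussian_denoise(noisy)
        rmse_noisy = np.sqrt(np.mean((noisy.samples - clean.samples) ** 2))
        rmse_denoised = np.sqrt(np.mean((denoised.samples - clean.samples) ** 2))
        assert rmse_denoised < rmse_noisy

    def test_component_invariants_hold_on_any_fit(self, cohort_varying):
        beat = cohort_varying.beats[0]
        _, d = gaussian_denoise(beat)
        a = d.amplitudes
        assert all(a[r] < a["forward_1"] for r in ("reflect_1", "reflect_2", "reflect_3"))
        assert a["reflect_1"] >= a["reflect_2"] >= a["reflect_3"]
        c = d.centers
        assert c["reflect_1"] <= c["reflect_2"] <= c["reflect_3"]
        assert all(v > 0 for v in a.values())

    def test_refit_of_own_output_is_stable(self):
        _, beat = make_admissible_beat(ADMISSIBLE_BEAT_PARAMS[1])
        denoised, d1 = gaussian_denoise(beat)
        _, d2 = gaussian_denoise(denoised)
        assert abs(d2.rmse - d1.rmse) < 1e-4

    def test_unnormalized_beat_rejected(self):
        beat = PulseBeat(samples=3.0 * np.sin(np.linspace(0, np.pi, 200)), fs=FS, HR=1.2)
        with pytest.raises(DataError):
            gaussian_denoise(beat)


class TestPipelineOrder:
    def test_normalization_must_precede_median_denoising(self):
        # a spike sets the normalization scale: removing it before vs after
        # normalizing yields different waveforms, so the documented order
        # (segment -> normalize -> denoise) is load-bearing
        y = np.sin(np.linspace(0, np.pi, 300))
        y[150] += 2.0
        beat = PulseBeat(samples=y, fs=FS, HR=1.2)
        norm_then_den = median_denoise(normalize_beat(beat), 15).samples
        den_then_norm = normalize_beat(median_denoise(beat, 15)).samples
        assert np.max(np.abs(norm_then_den - den_then_norm)) > 0.1


class TestSqiScreen:
    def _beats(self, n=10):
        _, beat = make_admissible_beat(ADMISSIBLE_BEAT_PARAMS[0])
        return [PulseBeat(samples=beat.samples.copy(), fs=FS, HR=1.22) for _ in range(n)]

    def test_identical_beats_all_pass(self):
        assert sqi_screen(self._beats()).all()

    def test_inverted_beat_fails(self):
        beats = self._beats(9)
        inv = beats[0].samples.max() - beats[0].samples
        beats.append(PulseBeat(samples=inv, fs=FS, HR=1.22))
        mask = sqi_screen(beats)
        assert mask[:9].all() and not mask[9]

    def test_mild_noise_passes_threshold(self):
        beats = []
        for i, b in enumerate(self._beats(8)):
            beats.append(
                PulseBeat(samples=add_noise(b.samples, 30.0, seed=i), fs=FS, HR=1.22)
            )
        assert sqi_screen(beats, threshold=0.86).all()

    def test_too_few_beats_rejected(self):
        with pytest.raises(ParameterError):
            sqi_screen(self._beats(2))


class TestResidualSnr:
    t = np.arange(0, 30, 1 / FS)
    clean = np.sin(2 * np.pi * 1.2 * t) + 0.4 * np.sin(2 * np.pi * 3.1 * t)

    def test_clean_in_band_signal_scores_high(self):
        assert estimate_residual_snr(self.clean, FS) > 40.0

    def test_known_15db_recovered_within_3db(self):
        ests = [
            estimate_residual_snr(add_noise(self.clean, 15.0, seed=s), FS)
            for s in range(20)
        ]
        assert np.all(np.abs(np.array(ests) - 15.0) < 3.0)

    def test_pure_noise_scores_negative(self):
        noise = np.random.default_rng(3).normal(size=self.t.size)
        assert estimate_residual_snr(noise, FS) < 0.0

    def test_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            estimate_residual_snr(self.clean[:100], FS)
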