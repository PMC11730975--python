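"""Stimulus generators: calibration, spectra, windows, and synthetic data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viscomfort import imagestats, ssvep, stimuli
from viscomfort.stimuli import (
    BumpSpec,
    CalibrationError,
    GratingSpec,
    SyntheticGroundTruth,
)


class TestGrating:
    def test_zero_contrast_is_uniform_midgray(self):
        img = stimuli.make_grating(GratingSpec(frequency=3, contrast=0, size=64), 30)
        assert np.allclose(img.pixels, 0.5)

    def test_spatial_period_follows_calibration(self):
        # 3 c/deg at 30 px/deg -> 10 px period along the modulation axis
        img = stimuli.make_grating(GratingSpec(frequency=3, size=100), 30)
        row = img.pixels[0]
        assert np.allclose(row[:-10], row[10:], atol=1e-12)

    def test_michelson_contrast_and_mean(self):
        img = stimuli.make_grating(GratingSpec(frequency=2.5, size=256, contrast=0.6), 32)
        mich = (img.pixels.max() - img.pixels.min()) / (
            img.pixels.max() + img.pixels.min()
        )
        assert mich == pytest.approx(0.6, abs=1e-3)
        assert img.pixels.mean() == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("freq", [0.75, 1.5, 3.0, 6.0, 9.0])
    def test_eeg_battery_frequencies_accepted(self, freq):
        img = stimuli.make_grating(GratingSpec(frequency=freq, size=128), 40.636)
        assert img.category == "grating"

    def test_nyquist_violation_rejected(self):
        with pytest.raises(CalibrationError):
            stimuli.make_grating(GratingSpec(frequency=10, size=64), 16)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        freq=st.floats(0.5, 7.0),
        contrast=st.floats(0.0, 1.0),
    )
    def test_range_and_mean_invariants(self, freq, contrast):
        img = stimuli.make_grating(
            GratingSpec(frequency=freq, size=64, contrast=contrast), 16
        )
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1
        assert abs(img.pixels.mean() - 0.5) < 0.05


class TestBumpNoise:
    def test_filter_gain_is_one_at_centre(self):
        gain = stimuli.raised_cosine_gain(np.array([3.0]), 3.0)
        assert gain[0] == 1.0

    def test_gain_support_edges(self):
        # flat out to (1-beta)/2T octaves, zero beyond (1+beta)/2T octaves
        flat_edge = 3.0 * 2 ** ((1 - 0.5) / (2 * 0.9))
        zero_edge = 3.0 * 2 ** ((1 + 0.5) / (2 * 0.9))
        g = stimuli.raised_cosine_gain(
            np.array([flat_edge * 0.999, zero_edge * 1.001]), 3.0
        )
        assert g[0] == pytest.approx(1.0, abs=1e-6)
        assert g[1] == 0.0

    def test_deterministic_given_seed(self):
        a = stimuli.make_bump_noise(BumpSpec(f0=3, size=64, seed=9), 30)
        b = stimuli.make_bump_noise(BumpSpec(f0=3, size=64, seed=9), 30)
        assert np.array_equal(a.pixels, b.pixels)

    def test_radial_spectrum_peaks_in_passband(self):
        img = stimuli.make_bump_noise(BumpSpec(f0=3, size=512, seed=4), 40.636)
        freqs, amp, _ = imagestats.radial_amplitude_spectrum(img)
        peak_f = freqs[np.argmax(amp)]
        # the passband is flat over +/- (1-beta)/2T octaves around f0, so
        # the single-realisation argmax lands inside it, and the gain at f0
        # itself equals the filter maximum
        assert abs(np.log2(peak_f / 3.0)) <= (1 - 0.5) / (2 * 0.9) + 0.05
        idx_f0 = np.argmin(np.abs(freqs - 3.0))
        assert amp[idx_f0] > 0.8 * amp.max()

    def test_energy_confined_to_filter_support(self):
        img = stimuli.make_bump_noise(BumpSpec(f0=2, size=256, seed=1), 32)
        spec = np.abs(np.fft.fft2(img.pixels)) ** 2
        fx = np.fft.fftfreq(256)[None, :] * 32
        fy = np.fft.fftfreq(256)[:, None] * 32
        f = np.hypot(fx, fy)
        support = stimuli.raised_cosine_gain(f, 2.0) > 0
        support[0, 0] = True  # DC carries the 0.5 background
        outside = spec[~support].sum() / spec.sum()
        assert outside < 0.01

    @pytest.mark.parametrize("f0", [0.1875, 0.375, 0.75, 1.5, 3.0, 6.0, 12.0])
    def test_model_battery_centre_frequencies_accepted(self, f0):
        import warnings

        with warnings.catch_warnings():
            # the 12 c/deg bump's roll-off legitimately brushes Nyquist
            warnings.simplefilter("ignore", UserWarning)
            img = stimuli.make_bump_noise(BumpSpec(f0=f0, size=64, seed=0), 40.636)
        assert img.category == "bump"

    def test_near_nyquist_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            stimuli.make_bump_noise(BumpSpec(f0=7, size=64, seed=0), 16)


class TestOneFNoise:
    def test_white_noise_has_flat_spectrum(self):
        img = stimuli.make_onef_noise(0.0, size=256, seed=1, ppd=40)
        k, valid = imagestats.spectral_slope(img)
        assert valid and abs(k) < 0.1

    def test_different_seeds_same_slope(self):
        slopes = []
        for seed in range(10):
            img = stimuli.make_onef_noise(-1.0, size=256, seed=seed, ppd=40)
            k, valid = imagestats.spectral_slope(img)
            assert valid
            slopes.append(k)
        a = stimuli.make_onef_noise(-1.0, 256, 0, 40)
        b = stimuli.make_onef_noise(-1.0, 256, 1, 40)
        assert not np.array_equal(a.pixels, b.pixels)
        assert abs(np.mean(slopes) + 1.0) < 0.1

    def test_exponent_bounds_enforced(self):
        with pytest.raises(ValueError):
            stimuli.make_onef_noise(-4.0, size=64, seed=0, ppd=40)


class TestGaussianWindow:
    def test_centre_unchanged_far_field_midgray(self):
        img = stimuli.make_onef_noise(-1, size=512, seed=3, ppd=40)
        win = stimuli.apply_gaussian_window(img, 150, 10.0)
        c = 255  # centre pixel of a 512 image grid centred at 255.5
        assert win.pixels[c, c] == img.pixels[c, c]
        assert abs(win.pixels[0, 0] - 0.5) < 1e-6  # corner >> flat + 5 sigma

    def test_window_too_large_rejected(self):
        img = stimuli.make_onef_noise(-1, size=128, seed=3, ppd=40)
        with pytest.raises(ValueError):
            stimuli.apply_gaussian_window(img, 100, 10.0)


class TestTemporalEnvelope:
    def test_frame_count_and_cycle_count(self):
        env = stimuli.temporal_contrast_envelope(5.0, 20.0, 60.0)
        assert len(env) == 1200
        # 100 full cycles: envelope returns to zero every 12 frames
        zeros = np.flatnonzero(np.isclose(env, 0.0, atol=1e-9))
        assert len(zeros) == 100 and zeros[1] - zeros[0] == 12

    def test_envelope_minimum_gives_midgray_stimulus(self, grating3):
        env = stimuli.temporal_contrast_envelope(5.0, 1.0, 60.0)
        frame = 0.5 + (grating3.pixels - 0.5) * env[0]
        assert np.allclose(frame, 0.5)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(rate=st.floats(1.0, 10.0), fr=st.floats(30.0, 120.0))
    def test_envelope_stays_in_unit_interval(self, rate, fr):
        if fr <= 2 * rate:
            with pytest.raises(ValueError):
                stimuli.temporal_contrast_envelope(rate, 2.0, fr)
        else:
            env = stimuli.temporal_contrast_envelope(rate, 2.0, fr)
            assert env.min() >= 0.0 and env.max() <= 1.0


class TestSyntheticRatings:
    def test_no_variation_gives_constant_rating(self):
        table = pd.DataFrame({"x": [0.0, 0.0, 0.0]})
        truth = SyntheticGroundTruth({"x": 0.0}, 0.0, 0.0, {}, intercept=4.0, seed=0)
        out = stimuli.generate_synthetic_ratings(table, truth, n_observers=3)
        assert (out["rating"] == 4.0).all()

    def test_eleven_observers_study_layout(self):
        table = pd.DataFrame({"x": np.linspace(-1, 1, 48)})
        truth = SyntheticGroundTruth({"x": 0.5}, 0.3, 0.5, {}, seed=1)
        out = stimuli.generate_synthetic_ratings(table, truth, n_observers=11)
        assert out["observer"].nunique() == 11
        assert len(out) == 48 * 11

    def test_ratings_respect_likert_bounds(self):
        table = pd.DataFrame({"x": np.linspace(-5, 5, 30)})
        truth = SyntheticGroundTruth({"x": 3.0}, 1.0, 2.0, {}, seed=2)
        out = stimuli.generate_synthetic_ratings(table, truth, n_observers=5)
        assert out["rating"].between(1, 7).all()
        disc = stimuli.generate_synthetic_ratings(
            table, truth, n_observers=5, discretize=True
        )
        assert set(disc["rating"]).issubset(set(range(1, 8)))

    def test_deterministic_given_seed(self):
        table = pd.DataFrame({"x": np.linspace(-1, 1, 10)})
        truth = SyntheticGroundTruth({"x": 0.5}, 0.3, 0.5, {}, seed=11)
        a = stimuli.generate_synthetic_ratings(table, truth, 4)
        b = stimuli.generate_synthetic_ratings(table, truth, 4)
        pd.testing.assert_frame_equal(a, b)


class TestSyntheticEEG:
    def test_montage_includes_posterior_channels(self):
        truth = SyntheticGroundTruth({}, ssvep_amplitude_map={"a": 1.0}, seed=0)
        rec = stimuli.generate_synthetic_eeg(["a"], truth, noise_rms_uv=0.0)
        for name in ("Oz", "O1", "O2", "POz"):
            assert name in rec.labels

    def test_pure_tone_peaks_at_five_hertz(self):
        truth = SyntheticGroundTruth({}, ssvep_amplitude_map={"a": 2.0}, seed=0)
        rec = stimuli.generate_synthetic_eeg(["a"], truth, noise_rms_uv=0.0)
        onset = rec.events[0][0]
        seg = rec.data[rec.channel_index("Oz"), onset : onset + 512][None, None, :]
        freqs, psd = ssvep.welch_psd(seg, fs=256.0)
        assert freqs[np.argmax(psd[0])] == pytest.approx(5.0)

    def test_reproducible_given_seed(self):
        truth = SyntheticGroundTruth({}, ssvep_amplitude_map={"a": 1.0}, seed=3)
        a = stimuli.generate_synthetic_eeg(["a"], truth)
        b = stimuli.generate_synthetic_eeg(["a"], truth)
        assert np.array_equal(a.data, b.data)
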