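"""Signal-conditioning stages: band-pass, detrend, mean filter,
normalization, interpolation and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eareog.core import GazeTrace
from eareog.preprocess import (
    bandpass,
    detrend_linear,
    interpolate_missing,
    mean_filter,
    normalize_unit,
    preprocess_camera_trial,
    preprocess_eog_trial,
    resample_to,
)

FS = 125.0


def _steady(x, frac=0.2):
    """Central part of a series, away from filter edge transients."""
    n = len(x)
    k = int(n * frac)
    return x[k : n - k]


def _tone_amplitude(x, freq_hz, fs=FS, trim=0.3):
    """Steady-state amplitude of a tone via quadrature projection on the
    central part of the series (edge transients excluded)."""
    n = len(x)
    k = int(n * trim)
    t = np.arange(n)[k : n - k] / fs
    return 2.0 * abs(np.mean(x[k : n - k] * np.exp(-2j * np.pi * freq_hz * t)))


def _analytic_bandpass_gain(freq_hz, low=0.1, high=15.0, order=5, fs=FS):
    """Magnitude response of the zero-phase (squared) Butterworth band-pass."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _w, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0])) ** 2  # forward-backward application squares |H|


class TestBandpass:
    def test_dc_is_stopband(self):
        out = bandpass(np.full(4000, 100.0), FS)
        assert np.max(np.abs(_steady(out))) < 1.0

    def test_1hz_passband_gain(self):
        t = np.arange(int(60 * FS)) / FS
        amp = _tone_amplitude(bandpass(np.sin(2 * np.pi * 1.0 * t), FS), 1.0)
        assert 0.95 <= amp <= 1.05
        assert amp == pytest.approx(_analytic_bandpass_gain(1.0), abs=0.02)

    def test_50hz_rejection(self):
        t = np.arange(int(60 * FS)) / FS
        amp = _tone_amplitude(bandpass(np.sin(2 * np.pi * 50.0 * t), FS), 50.0)
        assert amp < 0.02
        assert _analytic_bandpass_gain(50.0) < 1e-4

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        lhs = bandpass(2.0 * x + 3.0 * y, FS)
        rhs = 2.0 * bandpass(x, FS) + 3.0 * bandpass(y, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, low_hz=0.1, high_hz=70.0)
        with pytest.raises(ValueError):
            bandpass(np.zeros(10), FS)  # too short for order


class TestDetrend:
    def test_ramp_removed_exactly(self):
        t = np.arange(500) / FS
        out = detrend_linear(3.0 + 2.0 * t)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_whole_period_cosine_unchanged(self):
        # a cosine over whole periods is orthogonal to both the constant and
        # the time ramp (a sine-phase tone is not: it correlates with t)
        t = np.arange(int(4 * FS)) / FS
        x = np.cos(2 * np.pi * t)
        np.testing.assert_allclose(detrend_linear(x), x, atol=1e-2)

    def test_cosine_plus_ramp_recovered(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.cos(2 * np.pi * 0.5 * t)
        out = detrend_linear(x + 5.0 - 0.8 * t)
        np.testing.assert_allclose(out, x, atol=1e-2)

    def test_too_short(self):
        with pytest.raises(ValueError):
            detrend_linear(np.array([1.0]))


class TestMeanFilter:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(mean_filter(np.full(300, 7.0)), 7.0)

    def test_impulse_plateau(self):
        x = np.zeros(301)
        x[150] = 1.0
        out = mean_filter(x, 50)
        assert np.sum(out > 0) == 50
        np.testing.assert_allclose(out[out > 0], 1.0 / 50.0)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(42)
        out = mean_filter(rng.normal(size=10_000), 50)
        assert np.var(_steady(out)) == pytest.approx(1.0 / 50.0, rel=0.3)

    def test_length_preserved_and_positive_length_required(self):
        assert len(mean_filter(np.arange(10.0), 50)) == 10
        with pytest.raises(ValueError):
            mean_filter(np.arange(10.0), 0)


class TestNormalize:
    def test_affine_map(self):
        out, degen = normalize_unit(np.array([0.0, 2.0, 4.0]))
        assert not degen
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_symmetric_sine_unchanged(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 0.5 * t + 0.3)
        x = x - (x.max() + x.min()) / 2
        x = x / np.abs(x).max()
        out, _ = normalize_unit(x)
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_constant_flagged_degenerate(self):
        out, degen = normalize_unit(np.full(5, 5.0))
        assert degen
        np.testing.assert_array_equal(out, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=200)
    )
    def test_output_always_within_unit_interval(self, values):
        out, degen = normalize_unit(np.asarray(values))
        assert np.all(out >= -1.0 - 1e-12) and np.all(out <= 1.0 + 1e-12)
        if not degen:
            assert out.min() == pytest.approx(-1.0) and out.max() == pytest.approx(1.0)


class TestGazeInterpolation:
    def test_gap_in_ramp_restored(self):
        h = np.arange(20.0)
        valid = np.ones(20, bool)
        h2 = h.copy()
        h2[8:11] = np.nan
        valid2 = valid.copy()
        valid2[8:11] = False
        trace = GazeTrace(60.0, h2, np.zeros(20), valid2)
        out = interpolate_missing(trace)
        np.testing.assert_allclose(out.horizontal_deg, h, atol=1e-12)
        assert out.valid.all()

    def test_no_gaps_identity_and_leading_gap_propagates(self):
        h = np.array([np.nan, np.nan, 3.0, 4.0])
        trace = GazeTrace(60.0, h, np.zeros(4), np.array([0, 0, 1, 1], bool))
        out = interpolate_missing(trace)
        np.testing.assert_allclose(out.horizontal_deg, [3.0, 3.0, 3.0, 4.0])
        full = GazeTrace(60.0, np.arange(4.0), np.zeros(4))
        np.testing.assert_array_equal(
            interpolate_missing(full).horizontal_deg, full.horizontal_deg
        )

    def test_insufficient_valid_samples(self):
        trace = GazeTrace(60.0, np.array([1.0, np.nan, np.nan]), np.zeros(3), np.array([1, 0, 0], bool))
        with pytest.raises(ValueError):
            interpolate_missing(trace)


class TestResample:
    def test_ramp_exact(self):
        trace = GazeTrace(60.0, np.arange(60.0), np.zeros(60))
        out = resample_to(trace, 125.0)
        expected = out.times() * 60.0  # ramp slope is 60 deg per second here
        np.testing.assert_allclose(out.horizontal_deg, expected, atol=1e-9)

    def test_sine_interpolation_error_bound(self):
        t = np.arange(0, 6, 1 / 60.0)
        trace = GazeTrace(60.0, np.sin(2 * np.pi * 0.5 * t), np.zeros(len(t)))
        out = resample_to(trace, 125.0)
        truth = np.sin(2 * np.pi * 0.5 * out.times())
        assert np.max(np.abs(out.horizontal_deg - truth)) < 0.01

    def test_same_rate_identity(self):
        trace = GazeTrace(125.0, np.sin(np.arange(100) / 10), np.zeros(100))
        out = resample_to(trace, 125.0)
        np.testing.assert_allclose(out.horizontal_deg, trace.horizontal_deg, atol=1e-9)


class TestTrialChains:
    def test_eog_chain_reaches_unit_peaks(self):
        t = np.arange(int(6 * FS)) / FS
        x = 40.0 * np.sin(2 * np.pi * 0.5 * t) + 3.0 + 0.5 * t
        out, degen = preprocess_eog_trial(x)
        assert not degen
        assert out.min() == pytest.approx(-1.0) and out.max() == pytest.approx(1.0)

    def test_flat_channel_flagged(self):
        out, degen = preprocess_eog_trial(np.full(750, 3.0))
        assert degen and np.all(out == 0.0)

    def test_camera_chain_tracks_eog_chain(self):
        # same underlying sinusoid seen by both chains correlates > 0.99
        t60 = np.arange(0, 6, 1 / 60.0)
        cam = GazeTrace(60.0, 10 * np.sin(2 * np.pi * 0.5 * t60), np.zeros(len(t60)))
        t125 = np.arange(int(6 * FS)) / FS
        eog = 5.0 * np.sin(2 * np.pi * 0.5 * t125)
        cam_out, _ = preprocess_camera_trial(cam)
        eog_out, _ = preprocess_eog_trial(eog)
        m = min(len(cam_out), len(eog_out))
        r = np.corrcoef(cam_out[:m], eog_out[:m])[0, 1]
        # the camera chain's extra band-pass distorts the edges of a
        # 3-period window slightly, so the agreement is high but not perfect
        assert r > 0.97
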