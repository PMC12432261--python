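"""Saccade labeling, voltage deflections, waveform averaging and the
deflection–amplitude correlation."""

import numpy as np
import pytest

from eareog.montage import MontagePair
from eareog.saccades import (
    SaccadeEpoch,
    average_waveform,
    correlation_pvalue,
    deflection,
    deflection_amplitude_correlation,
    deflection_table,
    epoch_deflection,
    extract_epochs,
    interpolate_to_common_length,
    label_saccade,
    per_angle_mean_deflections,
)
from eareog.preprocess import mean_filter

FS = 125.0


def _smoothed_step(height, n=250, at=125, smooth=15, noise=0.0, seed=0):
    x = np.zeros(n)
    x[at:] = height
    x = mean_filter(x, smooth)
    if noise:
        x = x + np.random.default_rng(seed).normal(0.0, noise, n)
    return x


class TestLabelSaccade:
    def test_step_bracketed_with_clean_plateaus(self):
        x = _smoothed_step(-30.0)
        span = label_saccade(x, "left", FS)
        assert span is not None
        start, end = span
        assert start < 125 < end
        assert np.mean(x[:start]) == pytest.approx(0.0, abs=1.0)
        assert np.mean(x[end:]) == pytest.approx(-30.0, abs=1.0)

    def test_pure_noise_invalid(self):
        rng = np.random.default_rng(1)
        assert label_saccade(rng.normal(0, 2.0, 250), "left", FS) is None

    def test_flat_window_invalid(self):
        assert label_saccade(np.zeros(250), "right", FS) is None

    def test_direction_sign_must_match(self):
        # a rightward (positive) step is not a valid leftward saccade
        x = _smoothed_step(+30.0)
        assert label_saccade(x, "left", FS) is None
        assert label_saccade(x, "right", FS) is not None

    @pytest.mark.parametrize("snr", [10.0, 30.0, 100.0])
    def test_onset_recovered_across_snr(self, snr):
        height = 30.0
        for seed in range(5):
            x = _smoothed_step(height, noise=height / snr, seed=seed)
            span = label_saccade(x, "right", FS)
            assert span is not None
            start, end = span
            mid = (start + end) / 2
            assert abs(mid - 125) <= 10  # transition center within 10 samples
            assert abs(start - 118) <= 15


class TestDeflection:
    def test_ideal_step_measures_plateau_difference(self):
        x = _smoothed_step(-35.0)
        start, end = label_saccade(x, "left", FS)
        assert deflection(x, start, end) == pytest.approx(-35.0, abs=1.5)

    def test_flat_series_zero(self):
        assert deflection(np.zeros(100), 10, 60) == 0.0

    def test_noise_averaging(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.concatenate([np.zeros(40), np.full(40, 10.0)]) + rng.normal(0, 1.0, 80)
            vals.append(deflection(x, 10, 70))
        assert np.mean(vals) == pytest.approx(10.0, abs=0.5)

    def test_short_span_is_nan(self):
        assert np.isnan(deflection(np.zeros(100), 10, 25))

    def test_flank_mode(self):
        x = np.concatenate([np.zeros(50), np.full(50, -20.0)])
        assert deflection(x, 45, 55, mode="flank") == pytest.approx(-20.0)

    def test_antisymmetric_under_pair_swap(self):
        window = {
            "L8": _smoothed_step(10.0),
            "R8": _smoothed_step(-10.0),
            "hEOG": _smoothed_step(40.0),
        }
        ep = SaccadeEpoch(0, 0, "right", 15.0, window, FS, start_idx=110, end_idx=140, valid=True)
        d1 = epoch_deflection(ep, MontagePair("L8", "R8"))
        d2 = epoch_deflection(ep, MontagePair("R8", "L8"))
        assert d1 == pytest.approx(-d2, rel=1e-12)


class TestAverageWaveform:
    def _epoch(self, offset, direction="right"):
        window = {"hEOG": _smoothed_step(20.0) + offset}
        return SaccadeEpoch(
            0, 0, direction, 10.0, window, FS, start_idx=110, end_idx=140, valid=True
        )

    def test_identical_epochs_zero_sd(self):
        mean, sd = average_waveform([self._epoch(0.0), self._epoch(0.0)], "hEOG")
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_baseline_offsets_cancel_exactly(self):
        m1, _ = average_waveform([self._epoch(0.0)], "hEOG")
        m2, _ = average_waveform([self._epoch(57.0)], "hEOG")
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            average_waveform([], "hEOG")


class TestInterpolateToCommonLength:
    def test_identity_when_already_at_length(self):
        x = np.sin(np.arange(100) / 10)
        np.testing.assert_allclose(interpolate_to_common_length(x, 100), x, atol=1e-12)

    def test_ramp_preserved(self):
        x = np.linspace(0.0, 5.0, 80)
        out = interpolate_to_common_length(x, 200)
        np.testing.assert_allclose(out, np.linspace(0.0, 5.0, 200), atol=1e-9)

    def test_step_position_preserved_in_relative_time(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        out = interpolate_to_common_length(x, 250)
        rel_in = 50 / 100
        rel_out = np.argmax(out >= 0.5) / 250
        assert abs(rel_in - rel_out) <= 1 / 100  # within one input sample
        with pytest.raises(ValueError):
            interpolate_to_common_length(x, 10)


class TestDeflectionCorrelation:
    def test_proportional_means_perfect_r(self):
        ear = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = deflection_amplitude_correlation(ear, 2.0 * ear)
        assert res.statistic == pytest.approx(1.0)
        res_neg = deflection_amplitude_correlation(ear, -2.0 * ear)
        assert res_neg.statistic == pytest.approx(-1.0)

    def test_p_value_for_r079_n6(self):
        # t = 0.79*sqrt(4)/sqrt(1-0.79^2) = 2.577, two-sided t(4) tail = 0.061
        assert correlation_pvalue(0.79, 6) == pytest.approx(0.061, abs=0.002)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            deflection_amplitude_correlation([1.0, 2.0], [1.0, 2.0])


class TestEndToEndEpochs:
    def test_expected_epoch_count_and_window(self, noiseless_saccade_run):
        schedule, filtered, _truth, _camera = noiseless_saccade_run
        epochs, skipped = extract_epochs(filtered, schedule)
        assert skipped == 0
        assert len(epochs) == 24
        assert all(len(ep.window["hEOG"]) == 250 for ep in epochs)

    def test_all_clean_epochs_labelled_valid(self, labelled_epochs):
        assert all(ep.valid for ep in labelled_epochs)

    def test_deflection_monotone_with_amplitude(self, labelled_epochs, best_pair):
        table = deflection_table(labelled_epochs, [best_pair])
        for direction in ("left", "right"):
            means = per_angle_mean_deflections(table, best_pair.label, direction)
            mags = np.abs(means.to_numpy())
            assert np.all(np.diff(mags) > 0)  # grows with amplitude

    def test_noiseless_linearity_and_gold_agreement(self, labelled_epochs, best_pair):
        table = deflection_table(labelled_epochs, [best_pair])
        sub = table[(table["axis"] == "horizontal") & table["valid"]]
        r = np.corrcoef(sub["angle_change_deg"], sub[best_pair.label])[0, 1]
        assert abs(r) > 0.999
        for direction in ("left", "right"):
            ear = per_angle_mean_deflections(table, best_pair.label, direction).abs()
            gold = per_angle_mean_deflections(table, "hEOG", direction).abs()
            res = deflection_amplitude_correlation(ear, gold)
            assert res.statistic > 0.99
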