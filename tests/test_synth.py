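"""Corneo-retinal dipole forward model and recording/camera simulators."""

import numpy as np
import pytest

from eareog.core import GazeTrace
from eareog.stimulus import pursuit_schedule, saccade_schedule, schedule_to_gaze
from eareog.synth import (
    SynthConfig,
    clean_channels,
    default_layout,
    dipole_potential,
    simulate_camera,
    simulate_recording,
    white_noise_sigma_for_snr,
)

ANGLE_GRID = np.arange(-15.0, 15.1, 2.5)


class TestDipolePotential:
    def test_midsagittal_symmetry_at_straight_gaze(self):
        # equidistant left/right electrodes see identical potential at 0°
        left = dipole_potential(0.0, 0.0, (-0.06, 0.0, 0.0))
        right = dipole_potential(0.0, 0.0, (0.06, 0.0, 0.0))
        assert left == pytest.approx(right, abs=1e-12)

    def test_mirror_antisymmetry(self):
        # mirroring gaze and electrodes through the mid-sagittal plane
        # negates the left-right differential potential
        for theta in (5.0, 12.5):
            d1 = dipole_potential(theta, 0.0, (-0.07, 0.02, 0.01)) - dipole_potential(
                theta, 0.0, (0.07, 0.02, 0.01)
            )
            d2 = dipole_potential(-theta, 0.0, (-0.07, 0.02, 0.01)) - dipole_potential(
                -theta, 0.0, (0.07, 0.02, 0.01)
            )
            assert d1 == pytest.approx(-d2, rel=1e-9)

    def test_small_angle_linearity(self):
        # differential potential vs horizontal angle is nearly linear
        layout = default_layout()
        diff = dipole_potential(ANGLE_GRID, 0.0, layout.position("L8")) - dipole_potential(
            ANGLE_GRID, 0.0, layout.position("R8")
        )
        slope, intercept = np.polyfit(ANGLE_GRID, diff, 1)
        resid = diff - (slope * ANGLE_GRID + intercept)
        r2 = 1.0 - resid.var() / diff.var()
        assert r2 > 0.99

    def test_electrode_at_eye_rejected(self):
        with pytest.raises(ValueError):
            dipole_potential(0.0, 0.0, (-0.035, 0.075, 0.0005))


class TestSimulateRecording:
    def test_noiseless_deterministic(self):
        sched = saccade_schedule(angles_deg=(15.0,), directions=("right",))
        cfg = SynthConfig(rng_seed=5).noiseless()
        rec1, truth1 = simulate_recording(sched, config=cfg)
        rec2, _ = simulate_recording(sched, config=cfg)
        for label in rec1.channels:
            np.testing.assert_array_equal(rec1.channels[label], rec2.channels[label])
        assert truth1.horizontal_deg.max() == pytest.approx(15.0)

    def test_seed_contract(self):
        sched = saccade_schedule(angles_deg=(5.0,), directions=("left",))
        rec_a, _ = simulate_recording(sched, config=SynthConfig(rng_seed=1))
        rec_b, _ = simulate_recording(sched, config=SynthConfig(rng_seed=1))
        rec_c, _ = simulate_recording(sched, config=SynthConfig(rng_seed=2))
        np.testing.assert_array_equal(rec_a.channels["L8"], rec_b.channels["L8"])
        assert not np.array_equal(rec_a.channels["L8"], rec_c.channels["L8"])

    def test_step_scales_with_dipole_moment(self):
        sched = saccade_schedule(angles_deg=(15.0,), directions=("right",))
        base = SynthConfig().noiseless()
        double = base.model_copy(update={"dipole_moment_uVm2": 2 * base.dipole_moment_uVm2})
        rec1, _ = simulate_recording(sched, config=base)
        rec2, _ = simulate_recording(sched, config=double)
        step1 = rec1.channels["hEOG"][-1] - rec1.channels["hEOG"][0]
        step2 = rec2.channels["hEOG"][-1] - rec2.channels["hEOG"][0]
        assert step2 == pytest.approx(2 * step1, rel=1e-9)

    def test_differential_linear_in_step_amplitude(self):
        # noiseless montage deflections are linear in the gaze step over the
        # 2.5-15° grid
        layout = default_layout()
        cfg = SynthConfig().noiseless()
        amps = np.array([2.5, 5.0, 7.5, 10.0, 12.5, 15.0])
        steps = []
        for amp in amps:
            gaze = GazeTrace(125.0, np.array([0.0, amp]), np.zeros(2))
            ch = clean_channels(gaze, layout, cfg)
            diff = ch["L8"] - ch["R8"]
            steps.append(diff[1] - diff[0])
        r = np.corrcoef(amps, steps)[0, 1]
        assert abs(r) > 0.999

    def test_geometric_ordering_of_cross_ear_pairs(self):
        # the cross-ear pair nearest the eyes (anterior, eye level) has the
        # largest noiseless pursuit signal amplitude
        sched = pursuit_schedule(
            amplitudes_deg=(15.0,), frequencies_hz=(0.5,), axes=("horizontal",), seed=0
        )
        rec, _ = simulate_recording(sched, config=SynthConfig().noiseless())
        amplitude = {
            label: np.ptp(rec.channels[pair[0]] - rec.channels[pair[1]])
            for label, pair in {
                "L8-R8": ("L8", "R8"),
                "L1-R1": ("L1", "R1"),
                "L2-R2": ("L2", "R2"),
            }.items()
        }
        assert max(amplitude, key=amplitude.get) == "L8-R8"


class TestSimulateCamera:
    def test_clean_camera_matches_truth(self):
        sched = pursuit_schedule(
            amplitudes_deg=(10.0,), frequencies_hz=(0.5,), axes=("horizontal",), seed=1
        )
        truth = schedule_to_gaze(sched)
        cfg = SynthConfig().noiseless().model_copy(update={"camera_latency_s": 0.0})
        cam = simulate_camera(truth, cfg)
        assert cam.sample_rate_hz == 60.0
        resampled_truth = np.interp(cam.times(), truth.times(), truth.horizontal_deg)
        np.testing.assert_allclose(cam.horizontal_deg, resampled_truth, atol=1e-6)

    def test_dropout_rate_binomial(self):
        truth = GazeTrace(125.0, np.zeros(12500), np.zeros(12500))
        cfg = SynthConfig(camera_dropout_prob=0.1, rng_seed=3)
        cam = simulate_camera(truth, cfg)
        n = len(cam)
        invalid = int((~cam.valid).sum())
        expected = 0.1 * n
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(invalid - expected) < 3 * sigma
        # invalid samples hold non-finite values
        assert np.all(~np.isfinite(cam.horizontal_deg[~cam.valid]))

    def test_dropout_of_one_rejected(self):
        with pytest.raises(Exception):
            SynthConfig(camera_dropout_prob=1.0)


def test_snr_calibration_matches_definition():
    sched = pursuit_schedule(
        amplitudes_deg=(10.0,), frequencies_hz=(0.5,), axes=("horizontal",), seed=0
    )
    sigma = white_noise_sigma_for_snr(sched, ("L8", "R8"), snr=10.0)
    cfg = SynthConfig().noiseless()
    rec, _ = simulate_recording(sched, config=cfg)
    rms = np.std(rec.channels["L8"] - rec.channels["R8"])
    assert rms / (sigma * np.sqrt(2)) == pytest.approx(10.0, rel=1e-6)
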