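"""Filtering, resampling, tip transformation, derivatives, visibility."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lapskill as lk
from lapskill.calibration import CameraCone, GripCalibration, TipCalibration
from lapskill.kinematics import (
    GRID_STEP,
    derivatives,
    grip_series,
    lowpass_zero_phase,
    make_grid,
    resample_20hz,
    tip_trajectory,
    visibility_series,
)


def tone_amplitude(y, f, fs):
    """Exact amplitude of a single tone by quadrature demodulation."""
    t = np.arange(y.size) / fs
    a = 2 * np.mean(y * np.sin(2 * np.pi * f * t))
    b = 2 * np.mean(y * np.cos(2 * np.pi * f * t))
    return float(np.hypot(a, b))


class TestLowpass:
    def test_dc_gain_is_unity(self):
        y = lowpass_zero_phase(np.full(200, 3.7), fs=20.0)
        np.testing.assert_allclose(y, 3.7, atol=1e-9)

    def test_passband_tone_preserved(self):
        t = np.arange(0, 60, 0.05)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_zero_phase(x, fs=20.0)
        assert tone_amplitude(y, 1.0, 20.0) >= 0.999

    def test_stopband_tone_attenuation_matches_squared_butterworth(self):
        # two-pass gain 1/(1 + (8/6)^8) = 0.091 at 8 Hz for fs = 20 Hz
        t = np.arange(0, 60, 0.05)
        x = np.sin(2 * np.pi * 8.0 * t)
        y = lowpass_zero_phase(x, fs=20.0)
        assert tone_amplitude(y, 8.0, 20.0) == pytest.approx(0.091, abs=0.01)

    def test_zero_phase(self):
        t = np.arange(0, 30, 0.05)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass_zero_phase(x, fs=20.0)
        xc = np.correlate(y, x, mode="full")
        assert int(np.argmax(xc)) - (x.size - 1) == 0

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="padding"):
            lowpass_zero_phase(np.ones(10), fs=20.0)

    def test_multichannel_matches_per_channel(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        y = lowpass_zero_phase(x, fs=20.0)
        for j in range(3):
            np.testing.assert_allclose(y[:, j], lowpass_zero_phase(x[:, j], fs=20.0))


class TestResample:
    def test_uniform_input_identity(self):
        t = np.arange(100) * 0.05
        v = np.sin(t)
        grid, out = resample_20hz(t, v)
        np.testing.assert_allclose(grid, t, atol=1e-12)
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_jittered_ramp_is_exact(self):
        rng = np.random.default_rng(1)
        t = np.sort(np.arange(100) * 0.05 + rng.normal(0, 0.005, 100))
        t[0] = 0.0
        v = 3.0 * t - 1.0  # affine: linear interpolation is exact
        grid, out = resample_20hz(t, v)
        np.testing.assert_allclose(out, 3.0 * grid - 1.0, atol=1e-12)

    def test_grid_step_exact_and_no_extrapolation(self):
        t = np.array([0.0, 0.031, 0.07, 0.12, 0.18, 0.21, 0.26])
        grid, _ = resample_20hz(t, np.ones_like(t))
        assert np.allclose(np.diff(grid), GRID_STEP)
        assert grid[-1] <= t[-1]

    def test_slerp_preserves_unit_norm(self):
        rng = np.random.default_rng(2)
        R = Rotation.random(50, rng=rng)
        t = np.arange(50) * 0.053
        grid, q = resample_20hz(t, R.as_quat(scalar_first=True), kind="slerp")
        np.testing.assert_allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-12)


class TestTipTrajectory:
    def test_zero_offset_is_identity(self):
        pos = np.random.default_rng(0).normal(size=(30, 3))
        quat = Rotation.random(30, rng=np.random.default_rng(1)).as_quat(scalar_first=True)
        tip, _ = tip_trajectory(pos, quat, TipCalibration(np.zeros(3), 0.0))
        np.testing.assert_allclose(tip, pos)

    def test_identity_orientation_translates_by_offset(self):
        pos = np.zeros((10, 3))
        quat = np.tile([1.0, 0, 0, 0], (10, 1))
        tip, euler = tip_trajectory(pos, quat, TipCalibration([0, 0, -2.5], 0.0))
        np.testing.assert_allclose(tip, np.tile([0, 0, -2.5], (10, 1)))
        np.testing.assert_allclose(euler, 0.0, atol=1e-12)

    def test_rotation_about_z_moves_offset(self):
        # 90 deg about world z with offset (1,0,0): tip at sensor + (0,1,0)
        q = Rotation.from_euler("z", 90, degrees=True).as_quat(scalar_first=True)
        tip, _ = tip_trajectory(np.zeros((1, 3)), q[None, :],
                                TipCalibration([1.0, 0, 0], 0.0))
        np.testing.assert_allclose(tip[0], [0, 1, 0], atol=1e-12)

    def test_euler_unwrapped_no_jumps(self):
        angles = np.linspace(0, 720, 400)  # two full revolutions of azimuth
        quat = Rotation.from_euler("z", angles[:, None],
                                   degrees=True).as_quat(scalar_first=True)
        _, euler = tip_trajectory(np.zeros((400, 3)), quat,
                                  TipCalibration(np.zeros(3), 0.0))
        assert np.all(np.abs(np.diff(euler, axis=0)) < 180.0)
        assert euler[-1, 0] == pytest.approx(720.0, abs=1e-6)


class TestDerivatives:
    def test_constant_and_ramp(self):
        v1, a1 = derivatives(np.full(50, 2.0))
        np.testing.assert_allclose(v1, 0.0, atol=1e-12)
        t = np.arange(50) * GRID_STEP
        v2, a2 = derivatives(2.0 * t)
        np.testing.assert_allclose(v2, 2.0, atol=1e-9)
        np.testing.assert_allclose(a2, 0.0, atol=1e-9)

    def test_quadratic_interior_acceleration_exact(self):
        t = np.arange(100) * GRID_STEP
        _, acc = derivatives(t ** 2)
        np.testing.assert_allclose(acc[2:-2], 2.0, atol=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            derivatives(np.ones(2))


class TestGripSeries:
    CAL = GripCalibration(((1.0, 30.0), (2.0, 0.0)))

    def test_constant_open_voltage(self):
        angle, vel, _ = grip_series(np.full(50, 1.0), self.CAL)
        np.testing.assert_allclose(angle, 30.0)
        np.testing.assert_allclose(vel, 0.0, atol=1e-12)

    def test_linear_sweep_gives_linear_angle(self):
        v = np.linspace(1.0, 2.0, 100)
        angle, _, _ = grip_series(v, self.CAL)
        np.testing.assert_allclose(np.diff(angle), angle[1] - angle[0], atol=1e-9)

    def test_square_wave_velocity_peaks_match_transitions(self):
        from lapskill.features import count_peaks
        v = np.full(200, 1.0)
        for k in range(20, 200, 40):  # 5 transitions to closed and back
            v[k:k + 20] = 2.0
        angle, vel, _ = grip_series(v, self.CAL)
        n_trans = int(np.sum(np.abs(np.diff(v)) > 0))
        assert count_peaks(np.abs(vel), 50.0) == n_trans


class TestVisibility:
    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        cone = CameraCone(apex=rng.normal(size=3), axis=rng.normal(size=3),
                          half_angle=35.0)
        scope_pos = np.tile(rng.normal(size=3), (10_000, 1))
        R = Rotation.random(rng=np.random.default_rng(5))
        scope_quat = np.tile(R.as_quat(scalar_first=True), (10_000, 1))
        tips = rng.uniform(-30, 30, size=(10_000, 3))

        got = visibility_series(tips, scope_pos, scope_quat, cone)

        expected = np.zeros(10_000, dtype=bool)
        for i, tip in enumerate(tips):  # direct per-point angle computation
            local = R.inv().apply(tip - scope_pos[i])
            q = local - cone.apex
            nq = np.linalg.norm(q)
            if nq == 0 or q @ cone.axis <= 0:
                continue
            ang = np.degrees(np.arccos(np.clip(q @ cone.axis / nq, -1, 1)))
            expected[i] = ang <= cone.half_angle
        assert np.array_equal(got, expected)


class TestPipeline:
    def test_rigid_motion_invariance(self, small_trial, calib):
        rec, _ = small_trial
        kin = lk.compute_kinematics(rec, calib)
        W = Rotation.from_euler("zyx", [25, -40, 10], degrees=True)
        shift = np.array([5.0, -3.0, 2.0])
        from lapskill.trial_io import PoseStream, TrialRecording
        streams = {}
        for ch, s in rec.streams.items():
            pos = W.apply(s.pos) + shift
            quat = (W * Rotation.from_quat(s.quat, scalar_first=True)
                    ).as_quat(scalar_first=True)
            streams[ch] = PoseStream(s.t, pos, quat)
        rec2 = TrialRecording(streams=streams, grip=rec.grip, meta=rec.meta)
        kin2 = lk.compute_kinematics(rec2, calib)
        for tool in ("maryland", "needle"):
            a, b = kin.tools[tool], kin2.tools[tool]
            pa = np.sum(np.linalg.norm(np.diff(a.tip_pos, axis=0), axis=1))
            pb = np.sum(np.linalg.norm(np.diff(b.tip_pos, axis=0), axis=1))
            assert pb == pytest.approx(pa, rel=1e-6)
            np.testing.assert_allclose(np.linalg.norm(a.lin_vel, axis=1),
                                       np.linalg.norm(b.lin_vel, axis=1),
                                       rtol=1e-5, atol=1e-6)
            assert np.array_equal(a.visible, b.visible)

    def test_velocity_integrates_to_net_displacement(self, small_kin):
        for tool in ("maryland", "needle"):
            tk = small_kin.tools[tool]
            net = tk.tip_pos[-1] - tk.tip_pos[0]
            integ = np.trapezoid(tk.lin_vel, dx=GRID_STEP, axis=0)
            scale = max(np.linalg.norm(net), 1.0)
            assert np.linalg.norm(integ - net) / scale < 1e-3

    def test_grid_and_sample_count_invariant(self, small_kin):
        assert np.allclose(np.diff(small_kin.t), GRID_STEP)
        T = small_kin.duration
        assert small_kin.n_samples == int(np.floor(T / GRID_STEP + 1e-9)) + 1
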