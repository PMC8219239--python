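"""Derived-series computations against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spiraltrem import (
    SpiralSimConfig,
    ValidationError,
    acceleration,
    curvature_and_centripetal,
    delta,
    gen_spiral,
    instantaneous_movement,
    summarize,
    tangential_acceleration,
    trajectory_angle,
    velocity,
)
from spiraltrem.kinematics import FEATURE_NAMES

from conftest import circle_recording, make_recording


class TestDelta:
    def test_adjacent_differences(self):
        d = delta([1.0, 2.0, 4.0])
        np.testing.assert_array_equal(d.values, [1.0, 2.0])
        assert d.valid_from == 1

    def test_constant_series_gives_zeros(self):
        np.testing.assert_array_equal(delta([5.0] * 4).values, np.zeros(3))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_delta_inverts_cumulative_sum(self, values):
        s = np.asarray(values)
        np.testing.assert_allclose(
            delta(np.concatenate(([0.0], np.cumsum(s)))).values, s, atol=1e-6
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            delta([1.0])


class TestVelocity:
    def test_uniform_x_motion_unit_speed(self):
        # 0.01 units/sample at fs=100 -> 1 unit/s
        rec = make_recording(np.arange(50) * 0.01, np.zeros(50), fs=100.0)
        _, _, speed = velocity(rec)
        np.testing.assert_allclose(speed.values, 1.0)

    def test_circle_speed_matches_omega_r(self):
        omega, R = 2 * np.pi / 5, 10.0
        _, _, speed = velocity(circle_recording(R, omega))
        assert np.mean(speed.values) == pytest.approx(omega * R, rel=5e-3)

    def test_stationary_pen_zero_speed(self):
        rec = make_recording(np.full(10, 3.0), np.full(10, 4.0))
        _, _, speed = velocity(rec)
        np.testing.assert_array_equal(speed.values, np.zeros(9))


class TestAcceleration:
    def test_uniform_motion_zero_acceleration(self):
        rec = make_recording(np.arange(50) * 0.3, np.arange(50) * 0.1)
        _, _, mag = acceleration(rec)
        np.testing.assert_allclose(mag.values, 0.0, atol=1e-9)

    def test_circle_matches_centripetal_closed_form(self):
        omega, R = 2 * np.pi / 5, 10.0
        _, _, mag = acceleration(circle_recording(R, omega))
        assert np.mean(mag.values) == pytest.approx(omega**2 * R, rel=1e-2)

    def test_quadratic_position_constant_acceleration(self):
        # x(t) = t^2: second difference of a quadratic is exact, ax = 2
        t = np.arange(100) / 100.0
        ax, _, _ = acceleration(make_recording(t**2, np.zeros(100), fs=100.0))
        np.testing.assert_allclose(ax.values, 2.0, rtol=1e-9)

    def test_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            acceleration(make_recording([0.0, 1.0], [0.0, 0.0]))


class TestTrajectoryAngle:
    def test_motion_along_plus_x(self):
        rec = make_recording(np.arange(10.0), np.zeros(10))
        np.testing.assert_allclose(trajectory_angle(rec).values, 0.0)

    def test_motion_along_plus_y(self):
        rec = make_recording(np.zeros(10), np.arange(10.0))
        np.testing.assert_allclose(trajectory_angle(rec).values, np.pi / 2)

    def test_circle_unwrapped_angle_advances_at_omega(self):
        omega = 2 * np.pi / 5
        theta = trajectory_angle(circle_recording(10.0, omega)).values
        steps = np.diff(np.unwrap(theta))
        assert np.mean(steps) == pytest.approx(omega / 100.0, rel=1e-2)

    def test_zero_displacement_carries_angle_forward(self):
        rec = make_recording([0.0, 1.0, 1.0, 1.0, 2.0], [0.0, 0.0, 0.0, 0.0, 0.0])
        theta = trajectory_angle(rec).values
        np.testing.assert_allclose(theta, 0.0)  # pauses inherit the +x heading

    def test_leading_zero_displacement_defaults_to_zero(self):
        rec = make_recording([1.0, 1.0, 1.0], [2.0, 2.0, 3.0])
        theta = trajectory_angle(rec).values
        assert theta[0] == 0.0
        assert theta[1] == pytest.approx(np.pi / 2)


class TestCurvature:
    def test_circle_radius_recovered(self):
        rho, cen = curvature_and_centripetal(circle_recording(5.0, 2 * np.pi / 5))
        assert np.median(rho.values) == pytest.approx(5.0, rel=1e-2)
        omega = 2 * np.pi / 5
        assert np.median(cen.values) == pytest.approx(omega**2 * 5.0, rel=1e-2)

    def test_straight_line_capped_radius_zero_centripetal(self):
        rec = make_recording(np.arange(20.0), np.arange(20.0) * 2)
        rho, cen = curvature_and_centripetal(rec)
        assert np.all(rho.values == 1e6)
        np.testing.assert_allclose(cen.values, 0.0, atol=1e-9)

    def test_archimedean_spiral_matches_closed_form(self):
        # r = b*theta: rho(theta) = b (theta^2+1)^{3/2} / (theta^2+2)
        cfg = SpiralSimConfig(spiral_a=0.0, spiral_b=6.0, n_turns=4,
                              tremor_amplitude=0.0, noise_sd=0.0, seed=0)
        rec = gen_spiral(cfg)
        rho, _ = curvature_and_centripetal(rec)
        n = len(rec)
        theta = 2 * np.pi * cfg.n_turns * np.arange(n) / n
        expected = cfg.spiral_b * (theta**2 + 1) ** 1.5 / (theta**2 + 2)
        mid = slice(n // 4, 3 * n // 4)
        np.testing.assert_allclose(
            rho.values[mid.start - 2: mid.stop - 2], expected[mid], rtol=2e-2
        )


class TestTangentialAcceleration:
    def test_constant_speed_circle_is_zero(self):
        ta = tangential_acceleration(circle_recording(10.0, 2 * np.pi / 5))
        np.testing.assert_allclose(ta.values, 0.0, atol=0.05)

    def test_linear_speed_ramp_recovers_slope(self):
        # x(t) = k t^2 / 2 -> speed = k t, tangential acceleration = k
        k, fs = 3.0, 100.0
        t = np.arange(1, 200) / fs
        ta = tangential_acceleration(make_recording(0.5 * k * t**2, np.zeros_like(t), fs=fs))
        np.testing.assert_allclose(ta.values, k, rtol=1e-6)

    def test_two_sample_recording_rejected(self):
        with pytest.raises(ValidationError):
            tangential_acceleration(make_recording([0.0, 1.0], [0.0, 0.0]))


class TestSummarize:
    def test_constant_pressure_zero_pressure_stds(self):
        rec = make_recording(np.arange(20.0), np.arange(20.0) ** 1.5,
                             pressure=np.full(20, 800.0))
        f = summarize(rec)
        assert f["std_p"] == 0.0
        assert f["std_dp"] == 0.0
        assert f["std_ddp"] == 0.0

    def test_pressure_stds_match_hand_computation(self):
        # pressure [100,102,101,105,103]; differences hand-derived
        p = [100.0, 102.0, 101.0, 105.0, 103.0]
        rec = make_recording(np.arange(5.0), np.arange(5.0) ** 2, pressure=p)
        f = summarize(rec)
        assert f["std_p"] == pytest.approx(np.std(p, ddof=1))
        assert f["std_dp"] == pytest.approx(np.std([2.0, -1.0, 4.0, -2.0], ddof=1))
        assert f["std_ddp"] == pytest.approx(np.std([-3.0, 5.0, -6.0], ddof=1))

    def test_feature_vector_complete_and_finite(self):
        f = summarize(gen_spiral(SpiralSimConfig(tremor_amplitude=2.0, seed=3)))
        assert set(f) == set(FEATURE_NAMES)
        vals = np.array(list(f.values()))
        assert np.all(np.isfinite(vals))
        stds = [v for k, v in f.items() if k.startswith("std_")]
        assert all(s >= 0 for s in stds)

    def test_tremor_raises_pressure_variability(self):
        base = SpiralSimConfig(tremor_amplitude=0.0, seed=11)
        trem = SpiralSimConfig(tremor_amplitude=8.0, seed=11)
        assert summarize(gen_spiral(trem))["std_p"] > summarize(gen_spiral(base))["std_p"]

    def test_coordinate_scaling_covariance(self):
        rec = gen_spiral(SpiralSimConfig(tremor_amplitude=1.0, seed=5))
        scaled = make_recording(3.0 * rec.x, 3.0 * rec.y, pressure=rec.pressure,
                                fs=rec.fs)
        f, g = summarize(rec), summarize(scaled)
        for key in ("mean_speed", "std_speed", "mean_accel", "std_accel"):
            assert g[key] == pytest.approx(3.0 * f[key], rel=1e-9)
        for key in ("mean_angle", "std_angle"):
            assert g[key] == pytest.approx(f[key], rel=1e-9)

    def test_deltas_never_cross_stroke_boundaries(self):
        # two surface strokes separated by an in-air jump; the jump must not
        # appear in any difference-based feature
        x = np.concatenate([np.arange(10.0), 1000.0 + np.arange(10.0)])
        status = [1] * 10 + [0] * 0 + [1] * 10
        rec_joined = make_recording(x, np.zeros(20), pen_status=[1] * 20)
        status = [1] * 10 + [0] * 3 + [1] * 10
        x_gap = np.concatenate([np.arange(10.0), np.full(3, 500.0), 1000.0 + np.arange(10.0)])
        rec_gap = make_recording(x_gap, np.zeros(23), pen_status=status)
        f_gap = summarize(rec_gap, surface_only=True)
        f_joined = summarize(rec_joined, surface_only=True)
        # within strokes dx is constant 1 -> std_dx = 0; crossing the gap would not be
        assert f_gap["std_dx"] == 0.0
        assert f_joined["std_dx"] > 0.0

    def test_in_air_pressure_excluded_by_default(self):
        cfg = SpiralSimConfig(tremor_amplitude=0.0, noise_sd=0.0, n_lifts=3, seed=7)
        rec = gen_spiral(cfg)
        f = summarize(rec, surface_only=True)
        assert f["std_p"] == 0.0  # constant on-surface pressure
        g = summarize(rec, surface_only=False)
        assert g["std_p"] > 0.0  # zeros from in-air samples inflate variability

    def test_too_short_recording_lists_missing_channels(self):
        rec = make_recording([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValidationError, match="ddp"):
            summarize(rec)
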