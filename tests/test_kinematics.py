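"""Kinematic signal derivation: magnitudes, angles, vertical accel/velocity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import preimpact as pi
from preimpact.errors import UsageError
from preimpact.kinematics import G, rotation_matrices

from conftest import make_recording


class TestMagnitude:
    @pytest.mark.parametrize("vec,expected", [
        ([0, -1, 0], 1.0),          # unit gravity
        ([0.6, 0.8, 0], 1.0),       # 3-4-5 triangle
        ([0, 0, 0], 0.0),           # ideal free fall
    ])
    def test_closed_forms(self, vec, expected):
        rec = make_recording(acc=np.tile(vec, (5, 1)))
        np.testing.assert_allclose(pi.magnitude(rec, "acc").values, expected,
                                   atol=1e-12)

    def test_unknown_channel(self, standing_recording):
        with pytest.raises(UsageError):
            pi.magnitude(standing_recording, "euler")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=3, max_size=3),
           st.lists(st.floats(-180, 180), min_size=3, max_size=3))
    def test_rotation_invariance(self, vec, angles):
        """The L2 norm is unchanged by any rotation applied to the 3-vector."""
        R = rotation_matrices(np.array([angles]))[0]
        rec1 = make_recording(acc=np.array([vec]))
        rec2 = make_recording(acc=np.array([R @ vec]))
        np.testing.assert_allclose(pi.magnitude(rec1, "acc").values,
                                   pi.magnitude(rec2, "acc").values,
                                   rtol=1e-9, atol=1e-12)


class TestPostureAngles:
    def test_upright_standing_is_zero(self, standing_recording):
        pitch, roll = pi.posture_angles(standing_recording)
        np.testing.assert_allclose(pitch.values, 0.0)
        np.testing.assert_allclose(roll.values, 0.0)

    def test_forward_fall_ends_prone(self, fall_trial):
        rec, lab = fall_trial
        pitch, _ = pi.posture_angles(rec)
        assert abs(pitch.values[rec.index_of_frame(lab.impact_frame)]) >= 60

    def test_constant_angles_give_constant_series(self):
        rec = make_recording(euler=np.tile([30.0, 10.0, -20.0], (50, 1)))
        pitch, roll = pi.posture_angles(rec)
        np.testing.assert_allclose(pitch.values, 30.0)   # EulerX by default
        np.testing.assert_allclose(roll.values, -20.0)   # EulerZ by default


class TestVerticalAcceleration:
    def test_gravity_cancels_in_any_fixed_orientation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            euler = np.tile(rng.uniform(-90, 90, 3), (20, 1))
            R = rotation_matrices(euler)[0]
            acc = np.tile(R.T @ np.array([0.0, -1.0, 0.0]), (20, 1))
            rec = make_recording(acc=acc, euler=euler)
            np.testing.assert_allclose(pi.vertical_acceleration(rec).values, 0.0,
                                       atol=1e-10)

    def test_ideal_free_fall_reads_g_downward(self):
        rec = make_recording(acc=np.zeros((20, 3)),
                             euler=np.tile([40.0, 10.0, -25.0], (20, 1)))
        np.testing.assert_allclose(pi.vertical_acceleration(rec).values, G)

    def test_upward_half_g_acceleration(self):
        # upright sensor accelerating upward at 0.5 g reads 1.5 g of support
        rec = make_recording(acc=np.tile([0.0, -1.5, 0.0], (20, 1)))
        np.testing.assert_allclose(pi.vertical_acceleration(rec).values, -0.5 * G)


class TestVerticalVelocity:
    def test_zero_acceleration_gives_zero_velocity(self, standing_recording):
        np.testing.assert_allclose(pi.vertical_velocity(standing_recording).values,
                                   0.0, atol=1e-12)

    def test_free_fall_closed_form(self):
        # 0.3 s of ideal free fall from rest: v = 9.81 * 0.3 = 2.943 m/s
        rec = make_recording(acc=np.zeros((31, 3)))
        v = pi.vertical_velocity(rec).values[-1]
        assert v == pytest.approx(9.81 * 0.3, rel=0.01)

    def test_stillness_reset_returns_velocity_to_zero(self):
        # 0.1 s free fall then >= 0.25 s stationary: the reset zeroes the integral
        acc = np.vstack([np.zeros((10, 3)), np.tile([0.0, -1.0, 0.0], (40, 1))])
        v = pi.vertical_velocity(make_recording(acc=acc)).values
        assert v[10] > 0.8            # carried momentum right after the drop
        assert abs(v[-1]) < 1e-9      # zeroed once stillness persists

    def test_reset_disabled_matches_cumulative_sum_oracle(self, fall_trial):
        rec, _ = fall_trial
        v = pi.vertical_velocity(rec, pi.ResetPolicy(enabled=False)).values
        av = pi.vertical_acceleration(rec).values
        dt = 1.0 / rec.sample_rate_hz
        oracle = np.concatenate([[0.0], np.cumsum((av[1:] + av[:-1]) / 2 * dt)])
        np.testing.assert_allclose(v, oracle, rtol=0, atol=1e-12)

    def test_static_recording_stays_within_band(self):
        # simulator noise defaults, any static posture: |VV| <= 0.05 m/s
        for task, seed in [("D01", 0), ("D11", 1), ("D17", 2)]:
            rec = pi.simulate_adl(task, seed=seed)
            assert np.abs(pi.vertical_velocity(rec).values).max() <= 0.05
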