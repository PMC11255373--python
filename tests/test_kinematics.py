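"""Flight-kinematic parameters against closed-form oracles."""

import math

import numpy as np
import pytest

from pierisflight.exceptions import UndefinedQuantityError
from pierisflight.kinematics import (
    WingbeatRecord,
    advance_ratio,
    ascent_angle,
    covered_distance,
    flight_curvature,
    mean_acceleration,
    mean_velocity,
    sinuosity,
    summarize_flight,
    turning_acceleration,
    turning_rate,
    wingbeat_frequency,
)
from pierisflight.smoothing import SmoothedStates
from pierisflight.synthetic import PathProfile, generate_flight_path


def _states(pos, vel, acc, dt=1.0 / 120.0):
    n = len(pos)
    return SmoothedStates(frame_index=np.arange(n), position=np.asarray(pos),
                          velocity=np.asarray(vel),
                          acceleration=np.asarray(acc),
                          estimated=np.zeros(n, dtype=bool), dt=dt)


def _circle(r=0.5, v=1.0, revolutions=1.0, dt=1.0 / 120.0, z=1.0):
    w = v / r
    T = 2 * math.pi * revolutions / w
    t = np.arange(int(round(T / dt)) + 1) * dt
    pos = np.column_stack([r * np.cos(w * t), r * np.sin(w * t),
                           np.full_like(t, z)])
    vel = np.column_stack([-r * w * np.sin(w * t), r * w * np.cos(w * t),
                           np.zeros_like(t)])
    acc = np.column_stack([-r * w ** 2 * np.cos(w * t),
                           -r * w ** 2 * np.sin(w * t), np.zeros_like(t)])
    return _states(pos, vel, acc, dt)


def _straight(v=1.7, n=240, dt=1.0 / 120.0, direction=(1.0, 0.0, 0.0),
              height=1.0):
    d = np.asarray(direction) / np.linalg.norm(direction)
    t = np.arange(n) * dt
    pos = np.array([0, 0, height]) + v * t[:, None] * d
    vel = np.tile(v * d, (n, 1))
    return _states(pos, vel, np.zeros((n, 3)), dt)


class TestBasicQuantities:
    def test_covered_distance_steps(self):
        pos = np.zeros((11, 3))
        pos[:, 0] = np.arange(11) * 0.2
        s = _states(pos, np.ones((11, 3)), np.zeros((11, 3)))
        assert covered_distance(s, burn_in=0) == pytest.approx(2.0)

    def test_covered_distance_circle(self):
        s = _circle(r=1.0, v=1.0)
        assert covered_distance(s, burn_in=0) == pytest.approx(
            2 * math.pi, rel=1e-3)

    def test_constant_velocity(self):
        s = _straight(v=1.7)
        assert mean_velocity(s) == pytest.approx(1.7)
        assert mean_acceleration(s) == pytest.approx(0.0, abs=1e-12)

    def test_circle_acceleration(self):
        s = _circle(r=0.5, v=1.0)
        assert mean_acceleration(s) == pytest.approx(2.0, rel=1e-9)

    def test_single_frame_error(self):
        s = _states(np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3)))
        with pytest.raises(UndefinedQuantityError):
            covered_distance(s)

    def test_smoothing_shrinks_covered_distance(self, rng):
        from pierisflight.smoothing import kalman_smooth
        from pierisflight.stereo import Trajectory3D

        t = np.arange(300) / 120.0
        truth = np.column_stack([1.2 * t, np.sin(2 * t), 1 + 0.1 * t])
        noisy = truth + rng.normal(0, 5e-3, truth.shape)
        traj = Trajectory3D(frame_index=np.arange(300), xyz=noisy,
                            valid=np.ones(300, bool), dt=1 / 120.0)
        sm = kalman_smooth(traj, q=1.0, r=25e-6)
        raw_states = _states(noisy, np.zeros((300, 3)), np.zeros((300, 3)))
        assert covered_distance(sm) < covered_distance(raw_states)


class TestAdvanceRatio:
    def test_ratio(self):
        assert advance_ratio(1.2, 10.0) == pytest.approx(0.12)

    def test_zero_velocity(self):
        assert advance_ratio(0.0, 8.0) == 0.0

    def test_missing_frequency_propagates(self):
        assert math.isnan(advance_ratio(1.0, float("nan")))
        assert math.isnan(advance_ratio(1.0, 0.0))


class TestTurning:
    def test_straight_with_tangential_acceleration(self):
        n = 240
        t = np.arange(n) / 120.0
        d = np.array([1.0, 0.0, 0.0])
        pos = 0.5 * 3.0 * t[:, None] ** 2 * d + np.array([0, 0, 1.0])
        vel = 3.0 * t[:, None] * d + 0.1 * d  # keep |v| > eps
        acc = np.tile(3.0 * d, (n, 1))
        s = _states(pos, vel, acc)
        assert turning_acceleration(s) == pytest.approx(0.0, abs=1e-9)

    def test_circle_centripetal(self):
        s = _circle(r=0.5, v=1.0)
        assert turning_acceleration(s) == pytest.approx(2.0, rel=1e-9)

    def test_circle_turning_rate(self):
        s = _circle(r=0.5, v=1.0)
        assert turning_rate(s) == pytest.approx(2.0, rel=1e-6)

    def test_right_angle_turn(self):
        dt = 1.0 / 120.0
        n1 = 60
        v = 1.0
        # two straight legs joined by one 90-degree velocity change
        vel = np.concatenate([np.tile([v, 0, 0], (n1, 1)),
                              np.tile([0, v, 0], (n1, 1))])
        pos = np.cumsum(np.vstack([np.zeros(3), vel[:-1] * dt]), axis=0)
        s = _states(pos + [0, 0, 1], vel, np.zeros((2 * n1, 3)), dt)
        expected = (math.pi / 2) / dt / (2 * n1 - 10 - 1)
        assert turning_rate(s) == pytest.approx(expected, rel=1e-9)


class TestShape:
    def test_straight_sinuosity(self):
        assert sinuosity(_straight()) == pytest.approx(1.0)

    def test_semicircle_sinuosity(self):
        s = _circle(r=1.0, v=1.0, revolutions=0.5)
        assert sinuosity(s, burn_in=0) == pytest.approx(2 / math.pi,
                                                        rel=1e-3)

    def test_closed_loop_sinuosity(self):
        s = _circle(r=0.5, v=1.0, revolutions=1.0)
        assert sinuosity(s, burn_in=0) == pytest.approx(0.0, abs=1e-2)

    def test_circle_curvature(self):
        s = _circle(r=0.25, v=1.0)
        assert flight_curvature(s) == pytest.approx(4.0, rel=1e-9)

    def test_straight_curvature(self):
        assert flight_curvature(_straight()) == pytest.approx(0.0,
                                                              abs=1e-9)


class TestAscentAngle:
    def test_horizontal_circle(self):
        assert ascent_angle(_circle()) == pytest.approx(0.0, abs=1e-9)

    def test_climb_45(self):
        s = _straight(direction=(1.0, 0.0, 1.0))
        assert ascent_angle(s) == pytest.approx(45.0, rel=1e-9)

    def test_vertical_ascent(self):
        s = _straight(direction=(0.0, 0.0, 1.0))
        assert ascent_angle(s) == pytest.approx(90.0, rel=1e-9)

    def test_absolute_flag(self):
        s = _straight(direction=(1.0, 0.0, -1.0))
        assert ascent_angle(s) == pytest.approx(-45.0, rel=1e-9)
        assert ascent_angle(s, absolute=True) == pytest.approx(45.0,
                                                               rel=1e-9)


class TestWingbeat:
    def test_frequency(self):
        rec = WingbeatRecord("t", 36, 3.0)
        assert wingbeat_frequency(rec) == pytest.approx(12.0)

    def test_gliding_zero(self):
        assert wingbeat_frequency(WingbeatRecord("t", 0, 2.0)) == 0.0

    def test_missing_count(self):
        assert math.isnan(wingbeat_frequency(WingbeatRecord("t", None, 2.0)))

    def test_zero_duration(self):
        with pytest.raises(ValueError):
            WingbeatRecord("t", 10, 0.0)


class TestSummarize:
    def test_straight_line_composite(self):
        v, h, T = 1.5, 1.0, 2.0
        n = int(T * 120) + 1
        s = _straight(v=v, n=n, height=h)
        rec = WingbeatRecord("t", 24, (n - 1) / 120.0)
        summ = summarize_flight(s, rec, trajectory_id="t")
        used = n - 10
        assert summ.flight_height == pytest.approx(h)
        assert summ.mean_velocity == pytest.approx(v)
        assert summ.mean_acceleration == pytest.approx(0, abs=1e-12)
        assert summ.covered_distance == pytest.approx(v * (used - 1) / 120.0)
        assert summ.sinuosity == pytest.approx(1.0)
        assert summ.turning_rate == pytest.approx(0, abs=1e-12)
        assert summ.flight_curvature == pytest.approx(0, abs=1e-12)
        assert summ.ascent_angle == pytest.approx(0, abs=1e-12)
        assert summ.advance_ratio == pytest.approx(
            v / summ.wingbeat_frequency)
        assert not summ.missing_fields

    def test_missing_wingbeats_flagged(self):
        summ = summarize_flight(_straight(), None, trajectory_id="t")
        assert math.isnan(summ.wingbeat_frequency)
        assert math.isnan(summ.advance_ratio)
        assert "wingbeat_frequency" in summ.missing_fields
        assert "advance_ratio" in summ.missing_fields

    def test_helix_closed_forms(self):
        profile = PathProfile(kind="helix", speed=1.5, radius=0.5,
                              pitch=0.15, duration=3.0)
        _, truth = generate_flight_path(profile)
        a, b = 0.5, 0.15
        assert truth.mean_velocity == pytest.approx(1.5, rel=1e-6)
        assert truth.flight_curvature == pytest.approx(
            a / (a ** 2 + b ** 2), rel=1e-6)
        w = 1.5 / math.hypot(a, b)
        assert truth.mean_acceleration == pytest.approx(a * w ** 2,
                                                        rel=1e-6)
        assert truth.turning_acceleration == pytest.approx(a * w ** 2,
                                                           rel=1e-6)


class TestInvariances:
    def _helix_states(self):
        t = np.arange(300) / 120.0
        a, b, w = 0.4, 0.1, 2.5
        pos = np.column_stack([a * np.cos(w * t), a * np.sin(w * t),
                               1 + b * w * t])
        vel = np.column_stack([-a * w * np.sin(w * t),
                               a * w * np.cos(w * t),
                               np.full_like(t, b * w)])
        acc = np.column_stack([-a * w ** 2 * np.cos(w * t),
                               -a * w ** 2 * np.sin(w * t),
                               np.zeros_like(t)])
        return _states(pos, vel, acc)

    @staticmethod
    def _rotate_z(states, angle, shift):
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        return SmoothedStates(
            frame_index=states.frame_index,
            position=states.position @ R.T + shift,
            velocity=states.velocity @ R.T,
            acceleration=states.acceleration @ R.T,
            estimated=states.estimated, dt=states.dt)

    def test_rigid_motion_invariance(self):
        s = self._helix_states()
        # translation must be horizontal: flight height is z-dependent
        r = self._rotate_z(s, 0.7, np.array([3.0, -2.0, 0.0]))
        a = summarize_flight(s, WingbeatRecord("t", 30, 2.5)).to_dict()
        b = summarize_flight(r, WingbeatRecord("t", 30, 2.5)).to_dict()
        for k, va in a.items():
            if isinstance(va, str):
                continue
            assert va == pytest.approx(b[k], abs=1e-9), k

    def test_time_rescaling(self):
        s = self._helix_states()
        c = 2.0
        fast = SmoothedStates(frame_index=s.frame_index,
                              position=s.position,
                              velocity=s.velocity * c,
                              acceleration=s.acceleration * c ** 2,
                              estimated=s.estimated, dt=s.dt / c)
        assert mean_velocity(fast) == pytest.approx(c * mean_velocity(s))
        assert turning_rate(fast) == pytest.approx(c * turning_rate(s),
                                                   rel=1e-6)
        assert mean_acceleration(fast) == pytest.approx(
            c ** 2 * mean_acceleration(s))
        assert turning_acceleration(fast) == pytest.approx(
            c ** 2 * turning_acceleration(s))
        assert sinuosity(fast) == pytest.approx(sinuosity(s))
        assert flight_curvature(fast) == pytest.approx(flight_curvature(s))
        assert covered_distance(fast) == pytest.approx(covered_distance(s))

    def test_circle_identities(self):
        s = _circle(r=0.4, v=1.3)
        v, tr = mean_velocity(s), turning_rate(s)
        assert turning_acceleration(s) == pytest.approx(v * tr, rel=5e-3)
        assert flight_curvature(s) == pytest.approx(tr / v, rel=5e-3)
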