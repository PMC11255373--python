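"""Per-trajectory flight-kinematic parameters.

Eleven parameters summarize each smoothed 3D trajectory: wingbeat
frequency, covered distance, flight height, mean velocity, mean
acceleration, advance ratio (metres advanced per wingbeat), turning
acceleration (centripetal component |v x a| / |v|), turning rate
(angular change of successive velocity directions), sinuosity
(straight start-to-end distance over covered distance, in [0, 1]),
flight curvature (frame-averaged kappa = |v x a| / |v|^3) and ascent
angle (signed angle of the velocity vector to the horizontal plane).

All averages are means of per-frame magnitudes, taken over the frames
remaining after burn-in trimming; velocities and accelerations come
from the Kalman state, never finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from pierisflight.exceptions import UndefinedQuantityError
from pierisflight.smoothing import BURN_IN_FRAMES, SmoothedStates

SPEED_EPS = 1e-6  # m/s; frames slower than this are excluded from
                  # direction-dependent parameters


@dataclass
class WingbeatRecord:
    """Manually counted wingbeats for one trajectory."""

    trajectory_id: str
    n_wingbeats: int | None
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_wingbeats is not None and self.n_wingbeats < 0:
            raise ValueError("n_wingbeats must be non-negative")


@dataclass
class FlightSummary:
    """The eleven flight parameters of one trajectory.

    ``advance_ratio`` and ``wingbeat_frequency`` are NaN when the
    wingbeat count is missing (flagged for downstream imputation).
    """

    trajectory_id: str
    wingbeat_frequency: float
    covered_distance: float
    flight_height: float
    mean_velocity: float
    mean_acceleration: float
    advance_ratio: float
    turning_acceleration: float
    turning_rate: float
    sinuosity: float
    flight_curvature: float
    ascent_angle: float
    n_frames_used: int
    missing_fields: list[str] = field(default_factory=list)

    @property
    def turning_rate_deg(self) -> float:
        return math.degrees(self.turning_rate)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)
               if f.name != "missing_fields"}
        out["turning_rate_deg"] = self.turning_rate_deg
        return out


def _included(states: SmoothedStates, burn_in: int):
    sl = states.included(burn_in)
    return (states.position[sl], states.velocity[sl],
            states.acceleration[sl])


def covered_distance(states: SmoothedStates,
                     burn_in: int = BURN_IN_FRAMES) -> float:
    """Sum of Euclidean distances between consecutive positions (m)."""
    pos, _, _ = _included(states, burn_in)
    if pos.shape[0] < 2:
        raise UndefinedQuantityError(
            "covered distance needs >= 2 frames after burn-in")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def mean_velocity(states: SmoothedStates,
                  burn_in: int = BURN_IN_FRAMES) -> float:
    """Mean per-frame speed |v| (m/s)."""
    _, vel, _ = _included(states, burn_in)
    return float(np.linalg.norm(vel, axis=1).mean())


def mean_acceleration(states: SmoothedStates,
                      burn_in: int = BURN_IN_FRAMES) -> float:
    """Mean per-frame acceleration magnitude |a| (m/s^2)."""
    _, _, acc = _included(states, burn_in)
    return float(np.linalg.norm(acc, axis=1).mean())


def flight_height(states: SmoothedStates,
                  burn_in: int = BURN_IN_FRAMES) -> float:
    """Mean z over included frames (m)."""
    pos, _, _ = _included(states, burn_in)
    return float(pos[:, 2].mean())


def advance_ratio(mean_vel: float, wingbeat_freq: float) -> float:
    """Mean velocity per wingbeat (m/wingbeat); NaN propagates."""
    if wingbeat_freq is None or not np.isfinite(wingbeat_freq) \
            or wingbeat_freq == 0:
        return float("nan")
    return mean_vel / wingbeat_freq


def _moving_mask(vel: np.ndarray) -> np.ndarray:
    speed = np.linalg.norm(vel, axis=1)
    mask = speed > SPEED_EPS
    if not mask.any():
        raise UndefinedQuantityError(
            f"all frames below the {SPEED_EPS} m/s speed threshold")
    return mask


def turning_acceleration(states: SmoothedStates,
                         burn_in: int = BURN_IN_FRAMES) -> float:
    """Mean centripetal acceleration |v x a| / |v| (m/s^2)."""
    _, vel, acc = _included(states, burn_in)
    mask = _moving_mask(vel)
    v, a = vel[mask], acc[mask]
    cross = np.cross(v, a)
    return float((np.linalg.norm(cross, axis=1)
                  / np.linalg.norm(v, axis=1)).mean())


def turning_rate(states: SmoothedStates,
                 burn_in: int = BURN_IN_FRAMES) -> float:
    """Mean angular change of successive velocity directions (rad/s)."""
    _, vel, _ = _included(states, burn_in)
    mask = _moving_mask(vel)
    v = vel[mask]
    if v.shape[0] < 2:
        raise UndefinedQuantityError("turning rate needs >= 2 moving frames")
    v1, v2 = v[:-1], v[1:]
    cross = np.linalg.norm(np.cross(v1, v2), axis=1)
    dot = np.einsum("ij,ij->i", v1, v2)
    angles = np.arctan2(cross, dot)
    return float(angles.mean() / states.dt)


def sinuosity(states: SmoothedStates,
              burn_in: int = BURN_IN_FRAMES) -> float:
    """Straight start-to-end distance over covered distance, in [0, 1]."""
    pos, _, _ = _included(states, burn_in)
    total = covered_distance(states, burn_in)
    if total <= 0:
        raise UndefinedQuantityError("zero covered distance")
    straight = float(np.linalg.norm(pos[-1] - pos[0]))
    return float(np.clip(straight / total, 0.0, 1.0))


def flight_curvature(states: SmoothedStates,
                     burn_in: int = BURN_IN_FRAMES) -> float:
    """Frame-averaged path curvature kappa = |v x a| / |v|^3 (1/m)."""
    _, vel, acc = _included(states, burn_in)
    mask = _moving_mask(vel)
    v, a = vel[mask], acc[mask]
    cross = np.linalg.norm(np.cross(v, a), axis=1)
    return float((cross / np.linalg.norm(v, axis=1) ** 3).mean())


def ascent_angle(states: SmoothedStates, burn_in: int = BURN_IN_FRAMES,
                 absolute: bool = False) -> float:
    """Mean signed angle of velocity to the horizontal plane (degrees).

    Descent is negative; with ``absolute=True`` the magnitude is
    averaged instead.
    """
    _, vel, _ = _included(states, burn_in)
    mask = _moving_mask(vel)
    v = vel[mask]
    ratio = np.clip(v[:, 2] / np.linalg.norm(v, axis=1), -1.0, 1.0)
    ang = np.degrees(np.arcsin(ratio))
    if absolute:
        ang = np.abs(ang)
    return float(ang.mean())


def wingbeat_frequency(rec: WingbeatRecord) -> float:
    """Average wingbeats per second (Hz); NaN when count is missing."""
    if rec.duration_s <= 0:
        raise UndefinedQuantityError("zero wingbeat-record duration")
    if rec.n_wingbeats is None:
        return float("nan")
    return rec.n_wingbeats / rec.duration_s


def summarize_flight(states: SmoothedStates,
                     rec: WingbeatRecord | None = None,
                     burn_in: int = BURN_IN_FRAMES,
                     trajectory_id: str | None = None) -> FlightSummary:
    """Assemble the eleven flight parameters for one trajectory.

    Component errors propagate; fields undefined only because of a
    missing wingbeat count come back as NaN with the field name listed
    in ``missing_fields``.
    """
    sl = states.included(burn_in)
    n_used = sl.stop - sl.start if sl.stop is not None else states.n_frames
    missing: list[str] = []
    if rec is not None:
        freq = wingbeat_frequency(rec)
    else:
        freq = float("nan")
    if not np.isfinite(freq):
        missing.append("wingbeat_frequency")
    mv = mean_velocity(states, burn_in)
    adv = advance_ratio(mv, freq)
    if not np.isfinite(adv):
        missing.append("advance_ratio")
    tid = trajectory_id or (rec.trajectory_id if rec is not None else "")
    return FlightSummary(
        trajectory_id=tid,
        wingbeat_frequency=freq,
        covered_distance=covered_distance(states, burn_in),
        flight_height=flight_height(states, burn_in),
        mean_velocity=mv,
        mean_acceleration=mean_acceleration(states, burn_in),
        advance_ratio=adv,
        turning_acceleration=turning_acceleration(states, burn_in),
        turning_rate=turning_rate(states, burn_in),
        sinuosity=sinuosity(states, burn_in),
        flight_curvature=flight_curvature(states, burn_in),
        ascent_angle=ascent_angle(states, burn_in),
        n_frames_used=int(n_used),
        missing_fields=missing,
    )
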