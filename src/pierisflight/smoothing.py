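"""Constant-acceleration Kalman filtering and RTS smoothing of 3D tracks.

Each spatial axis is filtered independently with a three-state
(position, velocity, acceleration) linear Kalman filter driven by
white-noise jerk of spectral density ``q`` (m^2/s^5) and observed with
measurement variance ``r`` (m^2).  A Rauch–Tung–Striebel backward pass
conditions every state on the whole trajectory.  Frames without a
measurement receive prediction-only updates, so missing positions are
estimated rather than dropped, and all downstream velocities and
accelerations come from the smoothed state rather than finite
differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pierisflight.exceptions import NumericalFailureError
from pierisflight.stereo import Trajectory3D

logger = logging.getLogger(__name__)

#: frames trimmed from each end before summary statistics (edge effects)
BURN_IN_FRAMES = 5

DEFAULT_Q = 1.0      # m^2 / s^5
DEFAULT_R = 2.5e-5   # m^2  (5 mm measurement SD)


@dataclass
class SmoothedStates:
    """Kalman/RTS state estimates on a complete frame grid.

    ``estimated`` is True exactly where the input frame had no valid
    measurement and the state is model-predicted.
    """

    frame_index: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    estimated: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        for arr in (self.position, self.velocity, self.acceleration):
            if arr.shape != (n, 3):
                raise ValueError("state arrays must have shape (n, 3)")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("smoothed positions must be finite everywhere")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def included(self, burn_in: int = BURN_IN_FRAMES) -> slice:
        """Frame slice used for summary statistics (burn-in trimmed)."""
        n = self.n_frames
        if n <= 2 * burn_in + 1:
            return slice(0, n)
        return slice(burn_in, n - burn_in)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame_index,
            "x": self.position[:, 0], "y": self.position[:, 1],
            "z": self.position[:, 2],
            "vx": self.velocity[:, 0], "vy": self.velocity[:, 1],
            "vz": self.velocity[:, 2],
            "ax": self.acceleration[:, 0], "ay": self.acceleration[:, 1],
            "az": self.acceleration[:, 2],
            "estimated": self.estimated.astype(int),
        })


def _transition(dt: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    F = np.array([[1.0, dt, dt * dt / 2.0],
                  [0.0, 1.0, dt],
                  [0.0, 0.0, 1.0]])
    Q = q * np.array([
        [dt ** 5 / 20.0, dt ** 4 / 8.0, dt ** 3 / 6.0],
        [dt ** 4 / 8.0, dt ** 3 / 3.0, dt ** 2 / 2.0],
        [dt ** 3 / 6.0, dt ** 2 / 2.0, dt],
    ])
    return F, Q


def _filter_axis(z: np.ndarray, valid: np.ndarray, dt: float, q: float,
                 r: float, collect_loglik: bool = False):
    """Forward filter for one axis.  Returns filtered and predicted
    moments (and one-step predictive log-likelihood if requested)."""
    n = len(z)
    F, Q = _transition(dt, q)
    H = np.array([1.0, 0.0, 0.0])
    first = int(np.argmax(valid))
    x = np.array([z[first], 0.0, 0.0])
    P = np.diag([max(r, 1e-8), 25.0, 2500.0])
    xf = np.empty((n, 3))
    Pf = np.empty((n, 3, 3))
    xp = np.empty((n, 3))
    Pp = np.empty((n, 3, 3))
    loglik = 0.0
    n_meas = 0
    for k in range(n):
        if k == 0:
            xpk, Ppk = x, P
        else:
            xpk = F @ xf[k - 1]
            Ppk = F @ Pf[k - 1] @ F.T + Q
        xp[k], Pp[k] = xpk, Ppk
        if valid[k]:
            s = Ppk[0, 0] + r
            if s <= 0 or not np.isfinite(s):
                raise NumericalFailureError(
                    f"innovation variance not positive at frame {k}")
            innov = z[k] - xpk[0]
            K = Ppk[:, 0] / s
            xf[k] = xpk + K * innov
            Pf[k] = Ppk - np.outer(K, Ppk[0])
            # Joseph stabilization
            Pf[k] = (Pf[k] + Pf[k].T) / 2.0
            if collect_loglik and k > first:
                loglik += -0.5 * (np.log(2 * np.pi * s) + innov ** 2 / s)
                n_meas += 1
        else:
            xf[k], Pf[k] = xpk, Ppk
        if np.any(np.diag(Pf[k]) <= 0):
            raise NumericalFailureError(
                f"filter covariance lost positive definiteness at frame {k}")
    if collect_loglik:
        return xf, Pf, xp, Pp, loglik, n_meas
    return xf, Pf, xp, Pp


def _rts_axis(xf, Pf, xp, Pp, dt: float, q: float):
    n = xf.shape[0]
    F, _ = _transition(dt, q)
    xs = xf.copy()
    Ps = Pf.copy()
    for k in range(n - 2, -1, -1):
        C = Pf[k] @ F.T @ np.linalg.inv(Pp[k + 1])
        xs[k] = xf[k] + C @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Pf[k] + C @ (Ps[k + 1] - Pp[k + 1]) @ C.T
    return xs, Ps


def kalman_smooth(traj: Trajectory3D, q: float | None = None,
                  r: float | None = None,
                  smooth: bool = True) -> SmoothedStates:
    """Kalman-filter and RTS-smooth a raw trajectory.

    Parameters
    ----------
    traj : Trajectory3D
        Raw triangulated positions; must have >= 10 valid frames.
    q : float, optional
        Process-noise (white jerk) spectral density, m^2/s^5.
    r : float, optional
        Measurement-noise variance, m^2.  When either is None both are
        chosen by :func:`tune_noise` (falling back to defaults on short
        input).
    smooth : bool
        If False, return filter-only estimates (no backward pass); kept
        for sensitivity checks.
    """
    if traj.n_valid < 10:
        raise ValueError("need >= 10 valid frames to smooth")
    if q is None or r is None:
        try:
            q, r = tune_noise(traj)
        except ValueError:
            q, r = DEFAULT_Q, DEFAULT_R
    if q <= 0 or r <= 0:
        raise ValueError("q and r must be positive")
    # restrict to the observed span: interior gaps are estimated by the
    # model, but states are never extrapolated beyond the first/last
    # measurement (constant-acceleration coasting diverges quickly)
    vidx = np.flatnonzero(traj.valid)
    lo, hi = vidx[0], vidx[-1] + 1
    if lo > 0 or hi < len(traj.frame_index):
        traj = Trajectory3D(frame_index=traj.frame_index[lo:hi],
                            xyz=traj.xyz[lo:hi], valid=traj.valid[lo:hi],
                            dt=traj.dt)
    n = len(traj.frame_index)
    pos = np.empty((n, 3))
    vel = np.empty((n, 3))
    acc = np.empty((n, 3))
    for ax in range(3):
        xf, Pf, xp, Pp = _filter_axis(traj.xyz[:, ax], traj.valid,
                                      traj.dt, q, r)
        if smooth:
            xs, _ = _rts_axis(xf, Pf, xp, Pp, traj.dt, q)
        else:
            xs = xf
        pos[:, ax] = xs[:, 0]
        vel[:, ax] = xs[:, 1]
        acc[:, ax] = xs[:, 2]
    return SmoothedStates(frame_index=traj.frame_index.copy(), position=pos,
                          velocity=vel, acceleration=acc,
                          estimated=~traj.valid.copy(), dt=traj.dt)


def tune_noise(traj: Trajectory3D, grid_size: int = 5,
               span_decades: float = 2.0) -> tuple[float, float]:
    """Select (q, r) on a fixed log-spaced grid, deterministically.

    A pilot filter pass with default settings yields per-frame
    innovations; the median squared innovation centres the ``r`` grid
    and the default ``q`` centres the ``q`` grid.  The pair maximizing
    the one-step predictive log-likelihood (summed over axes) is
    returned.  A static (degenerate) trajectory falls back to the
    documented defaults with a warning.
    """
    if traj.n_valid < 50:
        raise ValueError("tune_noise needs >= 50 valid frames")
    z = traj.xyz[traj.valid]
    if float(np.max(np.var(z, axis=0))) < 1e-12:
        warnings.warn("static trajectory: falling back to default (q, r)",
                      stacklevel=2)
        return DEFAULT_Q, DEFAULT_R
    # pilot innovations
    innov2 = []
    for ax in range(3):
        xf, Pf, xp, Pp = _filter_axis(traj.xyz[:, ax], traj.valid, traj.dt,
                                      DEFAULT_Q, DEFAULT_R)
        v = traj.valid.copy()
        v[np.argmax(v)] = False  # skip the initialization frame
        innov2.append((traj.xyz[v, ax] - xp[v, 0]) ** 2)
    r_centre = float(np.median(np.concatenate(innov2)))
    r_centre = max(r_centre, 1e-12)
    half = span_decades / 2.0
    q_grid = DEFAULT_Q * np.logspace(-half, half, grid_size)
    r_grid = r_centre * np.logspace(-half, half, grid_size)
    best, best_ll = (q_grid[0], r_grid[0]), -np.inf
    for qc in q_grid:
        for rc in r_grid:
            ll = 0.0
            for ax in range(3):
                out = _filter_axis(traj.xyz[:, ax], traj.valid, traj.dt,
                                   qc, rc, collect_loglik=True)
                ll += out[4]
            if ll > best_ll:
                best_ll, best = ll, (float(qc), float(rc))
    logger.debug("tune_noise selected q=%.3g, r=%.3g (loglik %.2f)",
                 best[0], best[1], best_ll)
    return best
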