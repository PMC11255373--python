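"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: analytic flight
paths (with closed-form kinematics), stereo pixel tracks rendered
through the cage camera rig, calibration-wand sweeps, per-specimen wing
landmark configurations, and full cohorts with the hierarchical
statistical structure of the field study.

The default scene reproduces the recording geometry: a 6 x 2.5 x 2.5 m
outdoor cage filmed by two perpendicular cameras on 0.8 m tripods at
120 fps and 2560 x 1440 px, calibrated with a 24-cm two-point wand.
Cohort defaults reproduce the study composition (31 individuals, 106
trajectories, 26 spring / 80 summer tracks) and centre each group's
flight parameters and wing measurements on the study's reported
seasonal means.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from pierisflight.exceptions import (
    EmptyTrackError,
    GenerationError,
    InsufficientDataError,
)
from pierisflight.kinematics import (
    FlightSummary,
    WingbeatRecord,
    summarize_flight,
)
from pierisflight.morphometrics import WingLandmarks
from pierisflight.smoothing import SmoothedStates
from pierisflight.stereo import (
    CameraModel,
    PixelTrack2D,
    Trajectory3D,
    WandObservation,
    camera_from_pinhole,
    depth_sign,
    look_at_rotation,
    project,
)



# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Recording geometry and rendering noise model.

    Defaults are the study conditions: tunnel cage 6 x 2.5 x 2.5 m,
    two perpendicular cameras at 0.8 m height, 120 fps, 2560 x 1440 px.
    """

    cage: tuple[float, float, float] = (6.0, 2.5, 2.5)
    fps: float = 120.0
    image_width: int = 2560
    image_height: int = 1440
    camera_height: float = 0.8
    focal_px: float = 900.0
    camera_standoff: float = 2.0
    pixel_noise_px: float = 0.0
    dropout: float = 0.0
    k1: float = 0.0

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.cage[0] / 2.0, self.cage[1] / 2.0,
                         self.camera_height])

    def cameras(self) -> tuple[CameraModel, CameraModel]:
        """Ground-truth cameras: perpendicular viewing directions."""
        cx, cy, _ = self.cage
        h = self.camera_height
        pos1 = np.array([cx / 2.0, -self.camera_standoff, h])
        pos2 = np.array([-self.camera_standoff, cy / 2.0, h])
        centre_px = np.array([self.image_width / 2.0,
                              self.image_height / 2.0])
        cams = []
        for i, pos in enumerate((pos1, pos2), start=1):
            R = look_at_rotation(pos, self.centre)
            t = -R @ pos
            cams.append(camera_from_pinhole(
                self.focal_px, centre_px, R, t, self.image_width,
                self.image_height, k1=self.k1, id=f"cam{i}"))
        return tuple(cams)

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        ok = np.ones(len(xyz), dtype=bool)
        for ax in range(3):
            ok &= (xyz[:, ax] >= 0) & (xyz[:, ax] <= self.cage[ax])
        return ok


# ---------------------------------------------------------------------------
# flight paths
# ---------------------------------------------------------------------------

@dataclass
class PathProfile:
    """Parametric ground-truth flight path.

    ``kind`` is one of straight, circle, semicircle, helix, flutter,
    crw.  Analytic kinds carry closed-form velocity and acceleration;
    the correlated random walk (crw) carries numerically differentiated
    ground truth computed at generation time.
    """

    kind: str = "helix"
    speed: float = 1.5
    radius: float = 0.5
    pitch: float = 0.15           # helix rise per radian, m/rad
    flutter_amplitude: float = 0.02
    flutter_frequency: float = 12.0
    crw_speed_sd: float = 0.3
    crw_turn_concentration: float = 20.0
    duration: float = 3.0
    dt: float = 1.0 / 120.0
    start: tuple[float, float, float] = (3.0, 1.25, 1.2)
    heading: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"straight", "circle", "semicircle", "helix",
                             "flutter", "crw"}:
            raise ValueError(f"unknown path kind {self.kind!r}")
        if self.duration / self.dt < 20:
            raise ValueError("profile must span at least 20 frames")
        if self.speed <= 0:
            raise GenerationError("path speed must be positive")


def _analytic_states(profile: PathProfile) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray, np.ndarray]:
    """Positions, velocities and accelerations on the frame grid."""
    p = profile
    if p.kind == "semicircle":
        # exactly half a revolution regardless of requested duration
        duration = math.pi * p.radius / p.speed
    else:
        duration = p.duration
    n = max(int(round(duration / p.dt)) + 1, 21)
    t = np.arange(n) * p.dt
    start = np.asarray(p.start, dtype=float)
    if p.kind == "straight":
        d = np.asarray(p.heading, dtype=float)
        d = d / np.linalg.norm(d)
        pos = start + p.speed * t[:, None] * d
        vel = np.tile(p.speed * d, (n, 1))
        acc = np.zeros((n, 3))
    elif p.kind in ("circle", "semicircle"):
        w = p.speed / p.radius
        th = w * t
        centre = start + np.array([0.0, p.radius, 0.0])
        pos = centre + p.radius * np.column_stack(
            [np.sin(th), -np.cos(th), np.zeros(n)])
        vel = p.speed * np.column_stack(
            [np.cos(th), np.sin(th), np.zeros(n)])
        acc = p.radius * w ** 2 * np.column_stack(
            [-np.sin(th), np.cos(th), np.zeros(n)])
    elif p.kind == "helix":
        a, b = p.radius, p.pitch
        w = p.speed / math.hypot(a, b)
        th = w * t
        centre = start + np.array([0.0, a, 0.0])
        pos = centre + np.column_stack(
            [a * np.sin(th), -a * np.cos(th), b * th])
        vel = w * np.column_stack(
            [a * np.cos(th), a * np.sin(th), np.full(n, b)])
        acc = a * w ** 2 * np.column_stack(
            [-np.sin(th), np.cos(th), np.zeros(n)])
    elif p.kind == "flutter":
        d = np.asarray(p.heading, dtype=float)
        d[2] = 0.0
        d = d / np.linalg.norm(d)
        wf = 2.0 * math.pi * p.flutter_frequency
        pos = start + p.speed * t[:, None] * d
        pos[:, 2] += p.flutter_amplitude * np.sin(wf * t)
        vel = np.tile(p.speed * d, (n, 1))
        vel[:, 2] += p.flutter_amplitude * wf * np.cos(wf * t)
        acc = np.zeros((n, 3))
        acc[:, 2] = -p.flutter_amplitude * wf ** 2 * np.sin(wf * t)
    elif p.kind == "crw":
        rng = np.random.default_rng(p.seed)
        speeds = np.clip(rng.normal(p.speed, p.crw_speed_sd, n), 0.05, None)
        dphi = rng.vonmises(0.0, p.crw_turn_concentration, n)
        phi0 = math.atan2(p.heading[1], p.heading[0])
        phi = phi0 + np.cumsum(dphi) - dphi[0]
        pitch = rng.normal(0.0, 0.05, n)
        vel = speeds[:, None] * np.column_stack(
            [np.cos(phi) * np.cos(pitch), np.sin(phi) * np.cos(pitch),
             np.sin(pitch)])
        pos = start + np.vstack(
            [np.zeros(3), np.cumsum(vel[:-1] * p.dt, axis=0)])
        acc = np.gradient(vel, p.dt, axis=0)
    return t, pos, vel, acc


def generate_flight_path(profile: PathProfile,
                         scene: SceneConfig | None = None,
                         ) -> tuple[Trajectory3D, FlightSummary]:
    """Generate a ground-truth trajectory and its known flight summary.

    The summary is computed from the analytic (or, for crw, numerically
    differentiated) per-frame velocity and acceleration, independent of
    any reconstruction or smoothing.  Frames leaving the cage are
    truncated to ``valid=False`` with a warning.
    """
    t, pos, vel, acc = _analytic_states(profile)
    n = len(t)
    valid = np.ones(n, dtype=bool)
    if scene is not None:
        inside = scene.contains(pos)
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} frame(s) leave the cage; "
                "truncated to invalid", stacklevel=2)
            valid &= inside
    traj = Trajectory3D(frame_index=np.arange(n), xyz=pos, valid=valid,
                        dt=profile.dt)
    truth_states = SmoothedStates(
        frame_index=np.arange(n), position=pos, velocity=vel,
        acceleration=acc, estimated=np.zeros(n, dtype=bool), dt=profile.dt)
    rec = None
    if profile.kind == "flutter":
        duration = t[-1] - t[0]
        rec = WingbeatRecord(trajectory_id="truth",
                             n_wingbeats=int(round(
                                 profile.flutter_frequency * duration)),
                             duration_s=duration)
    # analytic states carry no estimation edge effects: no burn-in
    truth = summarize_flight(truth_states, rec, burn_in=0,
                             trajectory_id="truth")
    return traj, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_pixel_tracks(traj: Trajectory3D, scene: SceneConfig,
                        seed: int = 0) -> tuple[PixelTrack2D, PixelTrack2D]:
    """Project a trajectory through both cameras with noise and dropout.

    Per camera: points behind the camera or outside the sensor are
    flagged invalid; Gaussian pixel noise of ``scene.pixel_noise_px``
    is added; frames are dropped i.i.d. with ``scene.dropout``
    probability (mimicking frames where the subject could not be
    digitized).

    Raises
    ------
    EmptyTrackError
        If a camera never sees the subject.
    """
    rng = np.random.default_rng(seed)
    cams = scene.cameras()
    tracks = []
    for cam in cams:
        n = len(traj.frame_index)
        xy = np.full((n, 2), np.nan)
        valid = np.zeros(n, dtype=bool)
        vis = traj.valid & (depth_sign(traj.xyz, cam) > 0)
        if vis.any():
            uv = project(traj.xyz[vis], cam)  # includes distortion
            if scene.pixel_noise_px > 0:
                uv = uv + rng.normal(0.0, scene.pixel_noise_px, uv.shape)
            inframe = cam.in_frame(uv)
            xy[vis] = uv
            valid[vis] = inframe
        if scene.dropout > 0:
            keep = rng.random(n) >= scene.dropout
            valid &= keep
        xy[~valid] = np.nan
        if not valid.any():
            raise EmptyTrackError(
                f"subject never visible to camera {cam.id}")
        tracks.append(PixelTrack2D(camera_id=cam.id,
                                   frame_index=traj.frame_index.copy(),
                                   xy=xy, valid=valid))
    return tuple(tracks)


def generate_wand_sweep(scene: SceneConfig, wand_length: float = 0.24,
                        n_poses: int = 200, seed: int = 0,
                        margin: float = 0.6) -> WandObservation:
    """Random rigid poses of a two-point wand spanning the cage volume.

    Endpoint separation is exactly ``wand_length`` in 3D before
    projection; pixel noise follows ``scene.pixel_noise_px``.  Poses
    not fully visible in both cameras are rejected and resampled.
    """
    if n_poses < 30:
        raise InsufficientDataError("a wand sweep needs >= 30 poses")
    if wand_length >= min(scene.cage):
        raise GenerationError("wand does not fit in the cage")
    rng = np.random.default_rng(seed)
    cams = scene.cameras()
    lo = np.full(3, margin)
    hi = np.array(scene.cage) - margin
    pixels = np.empty((n_poses, 2, 2, 2))
    count = 0
    attempts = 0
    while count < n_poses:
        attempts += 1
        if attempts > 200 * n_poses:
            raise GenerationError(
                "could not place enough fully visible wand poses")
        centre = rng.uniform(lo, hi)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ends = np.stack([centre - d * wand_length / 2.0,
                         centre + d * wand_length / 2.0])
        ok = True
        uv_all = np.empty((2, 2, 2))
        for ci, cam in enumerate(cams):
            if np.any(depth_sign(ends, cam) <= 0):
                ok = False
                break
            uv = project(ends, cam)
            if scene.pixel_noise_px > 0:
                uv = uv + rng.normal(0.0, scene.pixel_noise_px, uv.shape)
            if not cam.in_frame(uv).all():
                ok = False
                break
            uv_all[ci] = uv
        if ok:
            pixels[count] = uv_all
            count += 1
    return WandObservation(pixels=pixels, wand_length=wand_length,
                           image_width=scene.image_width,
                           image_height=scene.image_height)


# ---------------------------------------------------------------------------
# wing landmarks
# ---------------------------------------------------------------------------

#: seasonal-form means and SDs of the generated wing measurements
#: (area mm^2, aspect ratio, outer-edge index, wing loading mm^3/mm^2).
#: SDs are population SDs reconstructed from the reported male-cohort
#: standard errors (SE * sqrt(N)).
MORPHO_FORM_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "spring": {
        "forewing_area_mm2": (225.6, 23.4),
        "aspect_ratio": (1.77, 0.057),
        "outer_edge_index": (1.11, 0.034),
        "wing_loading_mm": (0.0249, 0.0068),
    },
    "summer": {
        "forewing_area_mm2": (256.3, 33.6),
        "aspect_ratio": (1.73, 0.042),
        "outer_edge_index": (1.080, 0.025),
        "wing_loading_mm": (0.0209, 0.0066),
    },
}

#: species means/SDs of the marginal-region index (a species trait).
MORPHO_SPECIES_PARAMS: dict[str, tuple[float, float]] = {
    "P. napi": (0.72, 0.030),
    "P. rapae": (0.68, 0.024),
}

#: hindwing area as a fraction of forewing area (not reported; typical
#: pierid proportion) and thorax length/width ratio of the cylinder.
HINDWING_FRACTION = 0.8
THORAX_LENGTH_TO_WIDTH = 2.5

#: correlation between forewing area and aspect ratio across specimens
#: (larger wings tend to be relatively broader), matching the cohort
#: value observed in the field sample.
AREA_ASPECT_CORR = -0.4012

_OUTLINE_N = 64
_EDGE_ARC_DEG = (0.0, -100.0)   # ellipse angles spanned by landmarks 13..19
_LM9_ANGLE_DEG = -20.0


def _ellipse_lw(area_mm2: float, aspect: float,
                n: int = _OUTLINE_N) -> tuple[float, float]:
    """Length and width of an n-gon 'ellipse' with exact polygon area."""
    s = n * math.sin(2.0 * math.pi / n) / 8.0
    L = math.sqrt(aspect * area_mm2 / s)
    return L, L / aspect


def _ellipse_points(L: float, W: float, angles_rad: np.ndarray) -> np.ndarray:
    return np.column_stack([L / 2.0 + (L / 2.0) * np.cos(angles_rad),
                            (W / 2.0) * np.sin(angles_rad)])


def _edge_landmarks(L: float, W: float, target_index: float) -> np.ndarray:
    """Positions of landmarks 13..19 hitting the outer-edge index.

    Intermediate landmarks sit on perpendicular offsets from the 13-19
    chord, scaled by a bulge factor solved so that the polyline/chord
    ratio equals ``target_index`` exactly.
    """
    ang = np.radians(np.linspace(*_EDGE_ARC_DEG, num=7))
    base = _ellipse_points(L, W, ang)
    chord_a, chord_b = base[0], base[-1]
    u = chord_b - chord_a
    chord_len = np.linalg.norm(u)
    u = u / chord_len
    nvec = np.array([-u[1], u[0]])
    along = (base - chord_a) @ u
    feet = chord_a + along[:, None] * u
    h = (base - chord_a) @ nvec

    def index(beta: float) -> float:
        pts = feet + beta * h[:, None] * nvec
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
                     / chord_len)

    if target_index < 1.0:
        raise GenerationError(
            f"outer-edge index target {target_index} below 1 is infeasible")
    if target_index == 1.0:
        beta = 0.0
    else:
        hi = 1.0
        while index(hi) < target_index:
            hi *= 2.0
            if hi > 64:
                raise GenerationError(
                    f"outer-edge index target {target_index} unreachable "
                    "for this outline")
        beta = brentq(lambda b: index(b) - target_index, 0.0, hi,
                      xtol=1e-12)
    return feet + beta * h[:, None] * nvec


def generate_wing_landmarks(species: str, form: str, sex: str = "male",
                            seed: int = 0, specimen_id: str | None = None,
                            zero_variance: bool = False,
                            form_params: dict | None = None,
                            species_params: dict | None = None,
                            area_aspect_corr: float = AREA_ASPECT_CORR,
                            ) -> WingLandmarks:
    """Generate one specimen's 19-landmark wing configuration.

    A template forewing outline (elliptical n-gon) is deformed so that
    the specimen's outer-edge index, marginal-region index, forewing
    area and aspect ratio hit values drawn from the group's
    distribution (exact hits: the construction solves for them, it does
    not approximate).  ``zero_variance=True`` returns the group-mean
    specimen.
    """
    fp = (form_params or MORPHO_FORM_PARAMS).get(form)
    if fp is None:
        raise GenerationError(f"unknown seasonal form {form!r}")
    sp = (species_params or MORPHO_SPECIES_PARAMS).get(species)
    if sp is None:
        raise GenerationError(f"unknown species {species!r}")
    rng = np.random.default_rng(seed)

    def draw(mean, sd, lo):
        """Normal draw truncated (by resampling) to the feasible region."""
        if zero_variance:
            return mean
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if v > lo:
                return v
        raise GenerationError(
            f"could not draw a feasible value around mean {mean}")

    a_mean, a_sd = fp["forewing_area_mm2"]
    s_mean, s_sd = fp["aspect_ratio"]
    if zero_variance:
        area, aspect = a_mean, s_mean
    else:
        rho = float(np.clip(area_aspect_corr, -1.0, 1.0))
        for _ in range(1000):
            z1, z2 = rng.normal(size=2)
            area = a_mean + a_sd * z1
            aspect = s_mean + s_sd * (rho * z1
                                      + math.sqrt(1.0 - rho ** 2) * z2)
            if area > 50.0 and aspect > 1.02:
                break
        else:
            raise GenerationError("could not draw feasible area/aspect")
    edge = draw(*fp["outer_edge_index"], 1.0)
    wl_mm = draw(*fp["wing_loading_mm"], 1e-4)
    marginal = draw(*sp, 0.0)
    if area <= 50 or aspect <= 1.02 or wl_mm <= 1e-4:
        raise GenerationError(
            "morphology targets are infeasible "
            f"(area={area:.1f}, aspect={aspect:.2f}, loading={wl_mm:.4g})")
    marginal = float(np.clip(marginal, 0.05, 0.95))

    L, W = _ellipse_lw(area, aspect)
    outline_angles = np.linspace(0.0, 2.0 * math.pi, _OUTLINE_N,
                                 endpoint=False)
    # ensure vertices exactly at 0, 90, 180, 270 degrees so that width
    # and length are realized exactly
    outline = _ellipse_points(L, W, outline_angles)

    lms = np.full((19, 2), np.nan)
    lms[0] = (0.0, 0.0)                      # landmark 1: wing base
    edge_pts = _edge_landmarks(L, W, edge)   # landmarks 13..19
    lms[12:19] = edge_pts
    ang9 = math.radians(_LM9_ANGLE_DEG)
    lms[8] = marginal * L * np.array([math.cos(ang9), math.sin(ang9)])
    # filler landmarks along costa (2-8) and inner margin (10-12)
    costa = np.radians(np.linspace(160.0, 20.0, 7))
    lms[1:8] = _ellipse_points(L, W, costa)
    inner = np.radians(np.linspace(-150.0, -115.0, 3))
    lms[9:12] = _ellipse_points(L, W, inner)

    hw_area = HINDWING_FRACTION * area
    hL, hW = _ellipse_lw(hw_area, 1.3)
    hindwing = _ellipse_points(hL, hW, outline_angles)
    hindwing[:, 1] -= W  # placed below the forewing; position is cosmetic

    total_mm2 = 2.0 * (area + hw_area)
    volume_mm3 = wl_mm * total_mm2
    width = (4.0 * volume_mm3 / (THORAX_LENGTH_TO_WIDTH * math.pi)) ** (1 / 3)
    return WingLandmarks(
        specimen_id=specimen_id or f"{species}-{form}-{sex}-{seed}",
        landmarks=lms, forewing_outline=outline, hindwing_outline=hindwing,
        thorax_length_mm=THORAX_LENGTH_TO_WIDTH * width,
        thorax_width_mm=width,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: study composition: individuals per (species, form, sex)
STUDY_N_PER_GROUP: dict[tuple[str, str, str], int] = {
    ("P. napi", "spring", "male"): 3,
    ("P. napi", "summer", "male"): 11,
    ("P. rapae", "spring", "male"): 5,
    ("P. rapae", "summer", "male"): 7,
    ("P. napi", "spring", "female"): 1,
    ("P. napi", "summer", "female"): 2,
    ("P. rapae", "spring", "female"): 0,
    ("P. rapae", "summer", "female"): 2,
}

#: study track totals per (form, sex)
STUDY_TRACKS_PER_CELL: dict[tuple[str, str], int] = {
    ("spring", "male"): 22,
    ("summer", "male"): 67,
    ("spring", "female"): 4,
    ("summer", "female"): 13,
}

#: seasonal marginal means of the flight parameters (response scale).
#: Parameters without a reported seasonal difference share one mean.
FLIGHT_FORM_MEANS: dict[str, dict[str, float]] = {
    "spring": {
        "mean_velocity": 1.2,
        "mean_acceleration": 2.31,
        "turning_acceleration": 1.30,
        "flight_curvature": 3.80,
        "wingbeat_frequency": 12.0,
        "flight_height": 1.2,
        "turning_rate": 3.0,
        "sinuosity": 0.6,
        "covered_distance": 8.0,
    },
    "summer": {
        "mean_velocity": 1.7,
        "mean_acceleration": 3.43,
        "turning_acceleration": 2.34,
        "flight_curvature": 1.53,
        "wingbeat_frequency": 12.0,
        "flight_height": 1.2,
        "turning_rate": 3.0,
        "sinuosity": 0.6,
        "covered_distance": 8.0,
    },
}

LOGNORMAL_RESPONSES = tuple(FLIGHT_FORM_MEANS["spring"].keys())


@dataclass
class CohortConfig:
    """Hierarchical cohort generator settings.

    ``sigma_individual`` and ``sigma_residual`` are the SDs of the
    individual random intercept and the within-individual residual on
    the natural-log scale of each flight parameter.  Defaults mirror
    the study composition and the reported seasonal group means.
    """

    n_per_group: dict = field(
        default_factory=lambda: dict(STUDY_N_PER_GROUP))
    tracks_per_cell: dict = field(
        default_factory=lambda: dict(STUDY_TRACKS_PER_CELL))
    flight_means: dict = field(
        default_factory=lambda: {f: dict(v)
                                 for f, v in FLIGHT_FORM_MEANS.items()})
    sigma_individual: float = 0.20
    sigma_residual: float = 0.30
    ascent_sigma_individual: float = 3.0
    ascent_sigma_residual: float = 8.0
    n_missing_wingbeats: int = 4
    temperature_range: tuple[float, float] = (14.0, 36.0)
    temperature_mean: float = 19.0
    n_days: int = 16
    max_tracks_per_individual: int = 6
    seed: int = 0


@dataclass
class Cohort:
    """Generated cohort: specimen table, flight table, wingbeat records."""

    specimens: pd.DataFrame
    flights: pd.DataFrame
    wingbeats: pd.DataFrame
    landmarks: list[WingLandmarks]
    trajectories: dict | None = None


def _allocate_tracks(n_individuals: int, total: int,
                     cap: int) -> list[int]:
    """Deterministic 1..cap track allocation summing to ``total``."""
    if n_individuals == 0:
        return []
    if not n_individuals <= total <= cap * n_individuals:
        raise GenerationError(
            f"cannot allocate {total} tracks to {n_individuals} "
            f"individuals with 1..{cap} each")
    base = total // n_individuals
    rem = total - base * n_individuals
    return [base + (1 if i < rem else 0) for i in range(n_individuals)]


def _temperature_beta_params(lo: float, hi: float,
                             mean: float) -> tuple[float, float]:
    frac = (mean - lo) / (hi - lo)
    a = 1.5
    return a, a * (1.0 - frac) / frac


def generate_cohort(cfg: CohortConfig | None = None,
                    seed: int | None = None,
                    realize_paths: bool = False,
                    form_effect: bool = True) -> Cohort:
    """Generate a full study cohort with known hierarchical structure.

    Per flight parameter, each track value is
    ``exp(log(group mean) + b_individual + e)`` with the configured
    log-scale SDs (ascent angle, which carries sign, uses an additive
    normal model in degrees).  Advance ratio is derived as
    velocity / wingbeat frequency; ``cfg.n_missing_wingbeats`` tracks
    get a missing wingbeat count (NaN frequency and advance ratio).
    With ``form_effect=False`` both forms share the spring means
    (a null cohort for calibration studies).  With
    ``realize_paths=True`` each track additionally carries a helix
    trajectory whose closed-form speed and curvature equal the drawn
    targets.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    means = cfg.flight_means
    if not form_effect:
        means = {f: dict(means["spring"]) for f in means}
    for f, m in means.items():
        for k, v in m.items():
            if v <= 0:
                raise GenerationError(
                    f"unsatisfiable kinematic target {k}={v} for {f}")

    # individuals
    specimens = []
    landmarks = []
    sid = 0
    for (species, form, sex), n in sorted(cfg.n_per_group.items()):
        for _ in range(n):
            sid += 1
            specimens.append({
                "specimen_id": f"ind{sid:03d}", "species": species,
                "form": form, "sex": sex,
            })
    spec_df = pd.DataFrame(specimens)
    for _, row in spec_df.iterrows():
        landmarks.append(generate_wing_landmarks(
            row.species, row.form, row.sex,
            seed=int(rng.integers(2 ** 31)), specimen_id=row.specimen_id))

    # track allocation per (form, sex) cell
    spec_df["n_tracks"] = 0
    for (form, sex), total in cfg.tracks_per_cell.items():
        idx = spec_df.index[(spec_df.form == form) & (spec_df.sex == sex)]
        alloc = _allocate_tracks(len(idx), total,
                                 cfg.max_tracks_per_individual)
        spec_df.loc[idx, "n_tracks"] = alloc

    # recording days and temperatures
    a, b = _temperature_beta_params(*cfg.temperature_range,
                                    cfg.temperature_mean)
    lo, hi = cfg.temperature_range
    day_temp = lo + (hi - lo) * rng.beta(a, b, cfg.n_days)
    spec_day = rng.integers(0, cfg.n_days, len(spec_df))

    # individual random intercepts, one per response
    responses = list(LOGNORMAL_RESPONSES)
    b_ind = {r: rng.normal(0.0, cfg.sigma_individual, len(spec_df))
             for r in responses}
    b_ascent = rng.normal(0.0, cfg.ascent_sigma_individual, len(spec_df))

    rows = []
    trajectories = {} if realize_paths else None
    tid = 0
    for i, row in spec_df.iterrows():
        m = means[row.form]
        for _ in range(int(row.n_tracks)):
            tid += 1
            rec = {"trajectory_id": f"trk{tid:03d}",
                   "specimen_id": row.specimen_id, "species": row.species,
                   "form": row.form, "sex": row.sex,
                   "day": int(spec_day[i]),
                   "temperature_c": float(
                       day_temp[spec_day[i]] + rng.normal(0.0, 1.0))}
            for r in responses:
                val = math.exp(math.log(m[r]) + b_ind[r][i]
                               + rng.normal(0.0, cfg.sigma_residual))
                rec[r] = val
            rec["sinuosity"] = min(rec["sinuosity"], 0.98)
            rec["ascent_angle"] = float(
                b_ascent[i] + rng.normal(0.0, cfg.ascent_sigma_residual))
            rec["advance_ratio"] = (rec["mean_velocity"]
                                    / rec["wingbeat_frequency"])
            if realize_paths:
                kappa = rec["flight_curvature"]
                v = rec["mean_velocity"]
                ratio = 0.3  # pitch / radius of the realized helix
                a_r = 1.0 / (kappa * (1.0 + ratio ** 2))
                profile = PathProfile(
                    kind="helix", speed=v, radius=a_r,
                    pitch=ratio * a_r,
                    duration=max(rec["covered_distance"] / v, 0.5),
                    seed=int(rng.integers(2 ** 31)))
                traj, truth = generate_flight_path(profile)
                trajectories[rec["trajectory_id"]] = (traj, truth)
            rows.append(rec)
    flights = pd.DataFrame(rows)

    # missing wingbeat counts
    n_miss = min(cfg.n_missing_wingbeats, len(flights))
    miss_idx = rng.choice(len(flights), size=n_miss, replace=False)
    flights.loc[miss_idx, ["wingbeat_frequency", "advance_ratio"]] = np.nan

    durations = flights["covered_distance"] / flights["mean_velocity"]
    wb = pd.DataFrame({
        "trajectory_id": flights["trajectory_id"],
        "duration_s": durations,
        "n_wingbeats": np.where(
            flights["wingbeat_frequency"].notna(),
            np.round(flights["wingbeat_frequency"] * durations), np.nan),
    })
    return Cohort(specimens=spec_df, flights=flights, wingbeats=wb,
                  landmarks=landmarks, trajectories=trajectories)
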