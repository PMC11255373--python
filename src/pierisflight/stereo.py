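"""Stereo camera geometry: DLT cameras, calibration and triangulation.

The camera model is the classic 11-coefficient direct linear
transformation (DLT): world coordinates (metres) map to pixel
coordinates through

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)

optionally composed with a one-parameter radial distortion about the
geometric image centre.  Calibration is supported both from known 3D
points (linear least squares) and from tracked images of a rigid
two-point wand of known length moved through the volume (nonlinear
bundle adjustment); triangulation stacks the two cameras' DLT equations
and solves per frame by linear least squares.

Conventions: frames are 0-based; pixels are x-right / y-down; the world
frame is metric with z up and the ground plane at z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from pierisflight.exceptions import (
    CalibrationError,
    DegenerateProjectionError,
    InsufficientDataError,
    InvertibilityError,
    SingularSystemError,
)

logger = logging.getLogger(__name__)

#: condition-number threshold above which a triangulated frame is
#: flagged invalid (near-parallel viewing rays).
TRIANGULATION_COND_MAX = 1e8

MIN_WAND_FRAMES = 30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CameraModel:
    """11-coefficient DLT camera with optional radial distortion.

    Parameters
    ----------
    dlt : ndarray, shape (11,)
        Coefficients L1..L11 mapping world metres to pixels.
    k1 : float
        Radial distortion coefficient (dimensionless); radius is
        normalized by the half image diagonal about the image centre.
    image_width, image_height : int
        Sensor resolution in pixels.
    id : str
        Camera label.
    rms_residual : float or None
        RMS reprojection residual (px) of the calibration set used to
        fit the model, when fitted.
    """

    dlt: np.ndarray
    k1: float = 0.0
    image_width: int = 2560
    image_height: int = 1440
    id: str = "cam"
    rms_residual: float | None = None

    def __post_init__(self) -> None:
        self.dlt = np.asarray(self.dlt, dtype=float)
        if self.dlt.shape != (11,):
            raise ValueError("dlt must have exactly 11 coefficients")
        if np.linalg.matrix_rank(self.matrix) < 3:
            raise ValueError("DLT matrix is rank deficient")

    @property
    def matrix(self) -> np.ndarray:
        """3x4 projection matrix assembled from (L1..L11, 1)."""
        return np.append(self.dlt, 1.0).reshape(3, 4)

    @property
    def centre(self) -> np.ndarray:
        """Geometric image centre in pixels (distortion centre)."""
        return np.array([self.image_width / 2.0, self.image_height / 2.0])

    @property
    def norm_radius(self) -> float:
        """Half image diagonal, the radius normalization for ``k1``."""
        return float(np.hypot(*self.centre))

    def camera_centre(self) -> np.ndarray:
        """3D position of the camera's optical centre (null space)."""
        P = self.matrix
        _, _, vt = np.linalg.svd(P)
        c = vt[-1]
        return c[:3] / c[3]

    def in_frame(self, uv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside [0, width) x [0, height)."""
        uv = np.atleast_2d(uv)
        return (
            (uv[:, 0] >= 0)
            & (uv[:, 0] < self.image_width)
            & (uv[:, 1] >= 0)
            & (uv[:, 1] < self.image_height)
        )


@dataclass
class PixelTrack2D:
    """Per-camera pixel track of one point, with a validity mask."""

    camera_id: str
    frame_index: np.ndarray
    xy: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.frame_index)
        if self.xy.shape != (n, 2) or self.valid.shape != (n,):
            raise ValueError("inconsistent track array shapes")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValueError("frame_index must be strictly increasing")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class WandObservation:
    """Tracked endpoints of a rigid two-point calibration wand.

    ``pixels`` has shape (n_frames, 2 cameras, 2 endpoints, 2 coords);
    frames with any non-finite coordinate are treated as unusable.
    """

    pixels: np.ndarray
    wand_length: float = 0.24
    image_width: int = 2560
    image_height: int = 1440

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4 or self.pixels.shape[1:] != (2, 2, 2):
            raise ValueError("pixels must have shape (n, 2, 2, 2)")
        if self.wand_length <= 0:
            raise ValueError("wand_length must be positive")

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.pixels).all(axis=(1, 2, 3))

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass
class Trajectory3D:
    """Raw triangulated 3D positions on a fixed frame clock."""

    frame_index: np.ndarray
    xyz: np.ndarray
    valid: np.ndarray
    dt: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = len(self.frame_index)
        if self.xyz.shape != (n, 3) or self.valid.shape != (n,):
            raise ValueError("inconsistent trajectory array shapes")
        if np.any(~np.isfinite(self.xyz[self.valid])):
            raise ValueError("valid frames must have finite coordinates")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ---------------------------------------------------------------------------
# distortion
# ---------------------------------------------------------------------------

def distort(xy: np.ndarray, k1: float, centre: np.ndarray,
            norm_radius: float | None = None) -> np.ndarray:
    """Apply the one-parameter radial model x_d = c + (x_u - c)(1 + k1 r^2).

    ``r`` is the distance from the centre normalized by ``norm_radius``
    (default: the centre's own norm, i.e. the half image diagonal when
    the centre is the geometric image centre).
    """
    xy = np.asarray(xy, dtype=float)
    centre = np.asarray(centre, dtype=float)
    if norm_radius is None:
        norm_radius = float(np.hypot(*centre))
    d = xy - centre
    r2 = (d ** 2).sum(axis=-1, keepdims=True) / norm_radius ** 2
    return centre + d * (1.0 + k1 * r2)


def undistort(xy: np.ndarray, k1: float, centre: np.ndarray,
              norm_radius: float | None = None, tol: float = 1e-8,
              max_iter: int = 100) -> np.ndarray:
    """Invert :func:`distort` by fixed-point iteration to < `tol` px.

    Raises
    ------
    InvertibilityError
        If the iteration has not converged after ``max_iter`` steps
        (the radial map is not invertible for this ``k1`` over the
        image).
    """
    xy = np.asarray(xy, dtype=float)
    if k1 == 0.0:
        return xy.copy()
    centre = np.asarray(centre, dtype=float)
    if norm_radius is None:
        norm_radius = float(np.hypot(*centre))
    d = xy - centre
    u = d.copy()  # undistorted offset estimate
    for _ in range(max_iter):
        r2 = (u ** 2).sum(axis=-1, keepdims=True) / norm_radius ** 2
        u_new = d / (1.0 + k1 * r2)
        step = np.max(np.abs(u_new - u)) if u.size else 0.0
        u = u_new
        if step < tol:
            return centre + u
    raise InvertibilityError(
        f"radial undistortion did not converge in {max_iter} iterations "
        f"(k1={k1})"
    )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(points: np.ndarray, cam: CameraModel,
            apply_distortion: bool = True) -> np.ndarray:
    """Project world points (metres) to pixel coordinates.

    Raises
    ------
    DegenerateProjectionError
        If a point lies on the camera's principal plane (projection
        denominator numerically zero).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    L = cam.dlt
    den = pts @ L[8:11] + 1.0
    if np.any(np.abs(den) < 1e-12):
        raise DegenerateProjectionError("point on the camera's principal plane")
    u = (pts @ L[0:3] + L[3]) / den
    v = (pts @ L[4:7] + L[7]) / den
    uv = np.column_stack([u, v])
    if apply_distortion and cam.k1 != 0.0:
        uv = distort(uv, cam.k1, cam.centre, cam.norm_radius)
    if np.asarray(points).ndim == 1:
        return uv[0]
    return uv


def depth_sign(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Sign of the projective depth: positive for points in front."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    P = cam.matrix
    w = pts @ P[2, :3] + P[2, 3]
    return np.sign(np.linalg.det(P[:, :3])) * np.sign(w)


# ---------------------------------------------------------------------------
# pinhole construction (used by calibration and the scene renderer)
# ---------------------------------------------------------------------------

def look_at_rotation(position: np.ndarray, target: np.ndarray,
                     up: np.ndarray = (0.0, 0.0, 1.0)) -> np.ndarray:
    """World-to-camera rotation for a camera at `position` looking at
    `target`, with image y pointing down and `up` as world vertical."""
    position = np.asarray(position, dtype=float)
    forward = np.asarray(target, dtype=float) - position
    forward = forward / np.linalg.norm(forward)
    up = np.asarray(up, dtype=float)
    right = np.cross(forward, up)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    # rows: camera x (right), y (down in image), z (optical axis)
    return np.stack([right, down, forward])


def camera_from_pinhole(focal: float, centre: np.ndarray, R: np.ndarray,
                        t: np.ndarray, image_width: int = 2560,
                        image_height: int = 1440, k1: float = 0.0,
                        id: str = "cam") -> CameraModel:
    """Build a DLT :class:`CameraModel` from pinhole parameters.

    ``R`` and ``t`` are the world-to-camera rotation and translation
    (x_cam = R x_world + t); ``focal`` is in pixels, principal point at
    ``centre``.
    """
    centre = np.asarray(centre, dtype=float)
    K = np.array([[focal, 0.0, centre[0]],
                  [0.0, focal, centre[1]],
                  [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, np.asarray(t, dtype=float).reshape(3, 1)])
    if abs(P[2, 3]) < 1e-12:
        raise ValueError("camera centre on world origin plane; cannot "
                         "normalize DLT (translate the rig)")
    P = P / P[2, 3]
    return CameraModel(dlt=P.flatten()[:11], k1=k1,
                       image_width=image_width, image_height=image_height,
                       id=id)


# ---------------------------------------------------------------------------
# known-point DLT calibration
# ---------------------------------------------------------------------------

def dlt_calibrate(world_points: np.ndarray, pixel_points: np.ndarray,
                  image_width: int = 2560, image_height: int = 1440,
                  k1: float = 0.0, id: str = "cam") -> CameraModel:
    """Fit the 11 DLT coefficients from >= 6 non-coplanar correspondences.

    ``pixel_points`` must already be undistorted.  The fitted RMS
    reprojection residual (px) is stored on the returned model.

    Raises
    ------
    SingularSystemError
        Fewer than 6 points, or a coplanar / rank-deficient world
        configuration.
    """
    W = np.asarray(world_points, dtype=float)
    U = np.asarray(pixel_points, dtype=float)
    if W.ndim != 2 or W.shape[1] != 3 or U.shape != (W.shape[0], 2):
        raise ValueError("world_points must be (n,3) and pixel_points (n,2)")
    n = W.shape[0]
    if n < 6:
        raise SingularSystemError(
            f"DLT calibration needs >= 6 points, got {n}")
    centred = W - W.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise SingularSystemError(
            "calibration points are coplanar (world configuration spans "
            "fewer than 3 dimensions)")
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    A[0::2, 0:3] = W
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -U[:, [0]] * W
    b[0::2] = U[:, 0]
    A[1::2, 4:7] = W
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -U[:, [1]] * W
    b[1::2] = U[:, 1]
    L, *_ = np.linalg.lstsq(A, b, rcond=None)
    cam = CameraModel(dlt=L, k1=k1, image_width=image_width,
                      image_height=image_height, id=id)
    reproj = project(W, cam, apply_distortion=False)
    # per-coordinate RMS: ~sigma for i.i.d. pixel noise of SD sigma
    cam.rms_residual = float(np.sqrt(np.mean((reproj - U) ** 2)))
    return cam


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def triangulate_points(xy1: np.ndarray, xy2: np.ndarray, cam1: CameraModel,
                       cam2: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Linear DLT triangulation of paired (undistorted) pixel points.

    Returns (xyz, ok): positions and a mask that is False where the
    stacked system is ill-conditioned (near-parallel rays).
    """
    xy1 = np.atleast_2d(np.asarray(xy1, dtype=float))
    xy2 = np.atleast_2d(np.asarray(xy2, dtype=float))
    n = xy1.shape[0]
    xyz = np.full((n, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    Ls = (cam1.dlt, cam2.dlt)
    for i in range(n):
        A = np.empty((4, 3))
        b = np.empty(4)
        for c, (L, uv) in enumerate(zip(Ls, (xy1[i], xy2[i]))):
            u, v = uv
            A[2 * c] = L[0:3] - u * L[8:11]
            b[2 * c] = u - L[3]
            A[2 * c + 1] = L[4:7] - v * L[8:11]
            b[2 * c + 1] = v - L[7]
        if not np.all(np.isfinite(A)) or np.linalg.cond(A) > TRIANGULATION_COND_MAX:
            logger.debug("frame %d: ill-conditioned triangulation, skipped", i)
            continue
        xyz[i], *_ = np.linalg.lstsq(A, b, rcond=None)
        ok[i] = True
    return xyz, ok


def triangulate(track1: PixelTrack2D, track2: PixelTrack2D,
                cams: tuple[CameraModel, CameraModel],
                dt: float = 1.0 / 120.0) -> Trajectory3D:
    """Merge two synchronized 2D tracks into a 3D trajectory.

    Frames are valid only where both cameras have valid, well-
    conditioned observations; other frames carry ``valid=False`` and
    undefined positions, for the smoother to estimate.  Tracks must
    share a frame clock and be undistorted already.
    """
    if not np.array_equal(track1.frame_index, track2.frame_index):
        raise ValueError("tracks must share a frame clock")
    both = track1.valid & track2.valid
    xyz = np.full((len(both), 3), np.nan)
    valid = np.zeros(len(both), dtype=bool)
    if both.any():
        pts, ok = triangulate_points(track1.xy[both], track2.xy[both],
                                     cams[0], cams[1])
        xyz[both] = pts
        valid[both] = ok
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("%d frame(s) flagged invalid by the triangulation "
                        "condition threshold", n_bad)
    return Trajectory3D(frame_index=track1.frame_index.copy(), xyz=xyz,
                        valid=valid, dt=dt)


# ---------------------------------------------------------------------------
# wand calibration
# ---------------------------------------------------------------------------

@dataclass
class WandCalibrationResult:
    """Outcome of wand-based stereo calibration.

    Carries the two fitted cameras, the per-frame reconstructed wand
    lengths (the standard quality diagnostic: their SD relative to the
    wand length is the 'wand score'), and the bundle-adjustment
    reprojection RMS.
    """

    cameras: tuple[CameraModel, CameraModel]
    wand_lengths: np.ndarray
    rms_reprojection_px: float
    n_frames: int
    converged: bool
    wand_points: np.ndarray = field(repr=False, default=None)

    @property
    def mean_wand_length(self) -> float:
        return float(np.mean(self.wand_lengths))

    @property
    def sd_wand_length(self) -> float:
        return float(np.std(self.wand_lengths, ddof=1))

    def summary(self) -> str:
        return (
            f"Wand calibration over {self.n_frames} frames\n"
            f"  reconstructed wand length: {self.mean_wand_length:.5f} m "
            f"(SD {self.sd_wand_length:.2e} m)\n"
            f"  reprojection RMS: {self.rms_reprojection_px:.3f} px\n"
            f"  converged: {self.converged}"
        )


def _eight_point_essential(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Normalized 8-point estimate of the essential matrix.

    ``x1``/``x2`` are (n,2) points in normalized (unit-focal) image
    coordinates satisfying x2^T E x1 = 0.
    """
    def hartley(x):
        m = x.mean(axis=0)
        s = np.sqrt(2.0) / np.mean(np.linalg.norm(x - m, axis=1))
        T = np.array([[s, 0, -s * m[0]], [0, s, -s * m[1]], [0, 0, 1.0]])
        xh = np.column_stack([x, np.ones(len(x))]) @ T.T
        return xh, T

    h1, T1 = hartley(x1)
    h2, T2 = hartley(x2)
    A = np.column_stack([
        h2[:, 0] * h1[:, 0], h2[:, 0] * h1[:, 1], h2[:, 0],
        h2[:, 1] * h1[:, 0], h2[:, 1] * h1[:, 1], h2[:, 1],
        h1[:, 0], h1[:, 1], np.ones(len(h1)),
    ])
    _, _, vt = np.linalg.svd(A)
    E = T2.T @ vt[-1].reshape(3, 3) @ T1
    # enforce the (1, 1, 0) singular-value structure
    U, _, Vt = np.linalg.svd(E)
    return U @ np.diag([1.0, 1.0, 0.0]) @ Vt


def _triangulate_normalized(x1: np.ndarray, x2: np.ndarray, R: np.ndarray,
                            t: np.ndarray) -> np.ndarray:
    """Midpoint-free linear triangulation with P1=[I|0], P2=[R|t]."""
    P1 = np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = np.hstack([R, t.reshape(3, 1)])
    out = np.empty((len(x1), 3))
    for i, (a, b) in enumerate(zip(x1, x2)):
        A = np.stack([
            a[0] * P1[2] - P1[0],
            a[1] * P1[2] - P1[1],
            b[0] * P2[2] - P2[0],
            b[1] * P2[2] - P2[1],
        ])
        _, _, vt = np.linalg.svd(A)
        X = vt[-1]
        out[i] = X[:3] / X[3]
    return out


def _recover_pose(E: np.ndarray, x1: np.ndarray,
                  x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Choose the (R, t) decomposition of E by the cheirality test."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    best, best_count = None, -1
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for t in (U[:, 2], -U[:, 2]):
            X = _triangulate_normalized(x1, x2, R, t)
            z1 = X[:, 2]
            z2 = (X @ R.T + t)[:, 2]
            count = int(np.sum((z1 > 0) & (z2 > 0)))
            if count > best_count:
                best_count, best = count, (R, t)
    return best


def _pinhole_project(X: np.ndarray, f: float, centre: np.ndarray,
                     R: np.ndarray | None = None,
                     t: np.ndarray | None = None) -> np.ndarray:
    if R is not None:
        X = X @ R.T + t
    return f * X[:, :2] / X[:, 2:3] + centre


def wand_calibrate(obs: WandObservation,
                   vertical_ref: np.ndarray | None = None,
                   focal_guesses: tuple[float, ...] = (0.25, 0.5, 1.0),
                   max_nfev: int = 1000) -> WandCalibrationResult:
    """Jointly calibrate two cameras from a tracked two-point wand.

    Estimates both cameras' geometry (pinhole with principal point at
    the image centre, then expressed as DLT coefficients) and the 3D
    wand endpoints by sparse nonlinear least squares on the pixel
    reprojection error.  The gauge is fixed with the world frame
    centred on camera 1, metric scale set so that the mean
    reconstructed wand length equals ``obs.wand_length``, and the z
    axis aligned to ``vertical_ref`` when given (a pixel segment,
    bottom and top point in each camera, shape (2 cameras, 2 points,
    2 coords)); otherwise the rig's constructed vertical (image-up of
    camera 1) is used.

    Raises
    ------
    InsufficientDataError
        Fewer than 30 frames with both endpoints visible in both
        cameras.
    CalibrationError
        Optimizer failed to converge.
    """
    use = obs.usable
    n = int(use.sum())
    if n < MIN_WAND_FRAMES:
        raise InsufficientDataError(
            f"wand calibration needs >= {MIN_WAND_FRAMES} fully visible "
            f"frames, got {n}")
    px = obs.pixels[use]  # (n, cam, end, 2)
    centre = np.array([obs.image_width / 2.0, obs.image_height / 2.0])
    # correspondences: both endpoints pooled
    p1 = px[:, 0].reshape(-1, 2)  # camera 1, (2n, 2)
    p2 = px[:, 1].reshape(-1, 2)

    # --- initialization: essential matrix under a guessed focal -----------
    best_init, best_rms = None, np.inf
    for g in focal_guesses:
        f0 = g * obs.image_width
        x1 = (p1 - centre) / f0
        x2 = (p2 - centre) / f0
        E = _eight_point_essential(x1, x2)
        R, t = _recover_pose(E, x1, x2)
        X = _triangulate_normalized(x1, x2, R, t)
        r1 = _pinhole_project(X, f0, centre) - p1
        r2 = _pinhole_project(X, f0, centre, R, t) - p2
        rms = np.sqrt(np.mean(np.concatenate([r1, r2]) ** 2))
        if rms < best_rms:
            best_rms = rms
            best_init = (f0, R, t, X)
    f0, R0, t0, X0 = best_init

    # --- sparse bundle adjustment ------------------------------------------
    # params: [log f1, log f2, rotvec (3), t (3), X (3 per endpoint)].
    # The rigid wand constraint (every frame's endpoint separation equals
    # the known wand length) enters the cost directly: it selects the
    # metric member of the projective ambiguity family left by pure
    # reprojection error with unknown focal lengths, and pins the scale.
    t0 = t0 / np.linalg.norm(t0)
    X0 = _triangulate_normalized((p1 - centre) / f0, (p2 - centre) / f0,
                                 R0, t0)
    ends0 = X0.reshape(n, 2, 3)
    len0 = np.linalg.norm(ends0[:, 0] - ends0[:, 1], axis=1).mean()
    s0 = obs.wand_length / len0
    X0 = X0 * s0
    t0 = t0 * s0
    m = X0.shape[0]  # = 2n endpoints
    sigma_len = max(1e-3 * obs.wand_length, 1e-6)  # metres per unit residual
    x0 = np.concatenate([
        [np.log(f0), np.log(f0)],
        Rotation.from_matrix(R0).as_rotvec(),
        t0,
        X0.ravel(),
    ])

    def residuals(p):
        f1, f2 = np.exp(p[0]), np.exp(p[1])
        R = Rotation.from_rotvec(p[2:5]).as_matrix()
        t = p[5:8]
        X = p[8:].reshape(m, 3)
        r1 = (_pinhole_project(X, f1, centre) - p1).ravel()
        r2 = (_pinhole_project(X, f2, centre, R, t) - p2).ravel()
        ends = X.reshape(n, 2, 3)
        seps = np.linalg.norm(ends[:, 0] - ends[:, 1], axis=1)
        r_len = (seps - obs.wand_length) / sigma_len
        return np.concatenate([r1, r2, r_len])

    # jacobian sparsity: camera block dense, point blocks diagonal
    n_res = 4 * m + n
    S = sparse.lil_matrix((n_res, x0.size), dtype=np.int8)
    S[: 2 * m, 0] = 1                      # cam-1 residuals: f1
    S[2 * m: 4 * m, 1] = 1                 # cam-2 residuals: f2
    S[2 * m: 4 * m, 2:8] = 1               # cam-2 residuals: pose
    for j in range(m):
        cols = slice(8 + 3 * j, 11 + 3 * j)
        S[2 * j: 2 * j + 2, cols] = 1
        S[2 * m + 2 * j: 2 * m + 2 * j + 2, cols] = 1
    for j in range(n):                     # wand-length residuals
        S[4 * m + j, 8 + 6 * j: 8 + 6 * j + 6] = 1
    sol = least_squares(residuals, x0, jac_sparsity=S, method="trf",
                        x_scale="jac", ftol=1e-6, max_nfev=max_nfev)
    if not sol.success and sol.status <= 0:
        raise CalibrationError(
            f"wand bundle adjustment failed to converge "
            f"(final cost {sol.cost:.3g})")

    f1, f2 = np.exp(sol.x[0]), np.exp(sol.x[1])
    R2 = Rotation.from_rotvec(sol.x[2:5]).as_matrix()
    t2 = sol.x[5:8]
    X = sol.x[8:].reshape(m, 3)
    rms = float(np.sqrt(np.mean(sol.fun[: 4 * m] ** 2)))

    # metric scale from the adjusted wand points (mean length = wand length)
    ends = X.reshape(n, 2, 3)
    ba_lengths = np.linalg.norm(ends[:, 0] - ends[:, 1], axis=1)
    scale = obs.wand_length / ba_lengths.mean()
    X *= scale
    t2 = t2 * scale

    # --- gauge orientation: camera-1-centred, z up --------------------------
    R1 = np.eye(3)
    t1 = np.zeros(3)
    if vertical_ref is not None:
        vref = np.asarray(vertical_ref, dtype=float)
        # triangulate the two segment endpoints in the current frame
        seg, _ = _wand_triangulate_pair(vref, f1, f2, centre, R2, t2)
        up = seg[1] - seg[0]
    else:
        up = np.array([0.0, -1.0, 0.0])  # image-up of camera 1
    z_axis = up / np.linalg.norm(up)
    baseline = -R2.T @ t2  # camera-2 centre in the current frame
    x_axis = baseline - (baseline @ z_axis) * z_axis
    if np.linalg.norm(x_axis) < 1e-9:
        x_axis = np.array([1.0, 0.0, 0.0])
    x_axis = x_axis / np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)
    G = np.stack([x_axis, y_axis, z_axis])  # world' = G @ world
    X = X @ G.T
    R1g, t1g = R1 @ G.T, t1
    R2g, t2g = R2 @ G.T, t2
    # Origin: under the centroid of the calibration cloud, with z = 0 at
    # the lowest reconstructed point.  (The camera centre itself cannot
    # serve as origin: the DLT normalization is singular there.)
    offset = np.array([X[:, 0].mean(), X[:, 1].mean(), X[:, 2].min()])
    X = X - offset
    t1g = t1g + R1g @ offset
    t2g = t2g + R2g @ offset

    cam1 = camera_from_pinhole(f1, centre, R1g, t1g, obs.image_width,
                               obs.image_height, id="cam1")
    cam2 = camera_from_pinhole(f2, centre, R2g, t2g, obs.image_width,
                               obs.image_height, id="cam2")
    cam1.rms_residual = cam2.rms_residual = rms

    # diagnostic: re-triangulate the (noisy) wand pixels through the
    # fitted cameras, independently of the adjusted 3D points
    A, okA = triangulate_points(px[:, 0, 0], px[:, 1, 0], cam1, cam2)
    B, okB = triangulate_points(px[:, 0, 1], px[:, 1, 1], cam1, cam2)
    ok = okA & okB
    lengths = np.linalg.norm(A[ok] - B[ok], axis=1)
    return WandCalibrationResult(
        cameras=(cam1, cam2), wand_lengths=lengths,
        rms_reprojection_px=rms, n_frames=n,
        converged=bool(sol.success), wand_points=X.reshape(n, 2, 3),
    )


def _wand_triangulate_pair(segments: np.ndarray, f1: float, f2: float,
                           centre: np.ndarray, R2: np.ndarray,
                           t2: np.ndarray) -> tuple[np.ndarray, None]:
    """Triangulate a 2-point pixel segment seen in both cameras.

    ``segments`` has shape (2 cameras, 2 points, 2 coords).
    """
    x1 = (segments[0] - centre) / f1
    x2 = (segments[1] - centre) / f2
    return _triangulate_normalized(x1, x2, R2, t2), None
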