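"""CSV and text file formats for every pipeline stage.

3D-videography workflows traditionally exchange ad-hoc CSVs; this
module fixes one documented dialect per artefact and validates it on
read:

- track CSV (per camera):      frame, x_px, y_px (blank = not digitized)
- wand CSV (two cameras):      frame, c1_ax_px .. c2_by_px
- calibration text file:       11 DLT coefficients + k1 per camera
- smoothed-states CSV:         frame, x..z, vx..vz, ax..az, estimated
- flight-summary CSV:          one row per trajectory (all flight
                               parameters + specimen_id, species,
                               form, sex)
- landmark CSV:                specimen_id, landmark_id (1-19), x_mm, y_mm
- outline CSV:                 specimen_id, wing, vertex_index, x_mm, y_mm
- morpho-summary CSV:          one row per specimen

All readers raise :class:`~pierisflight.exceptions.SchemaError` naming
the offending file and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from pierisflight.exceptions import SchemaError
from pierisflight.morphometrics import N_LANDMARKS, WingLandmarks
from pierisflight.smoothing import SmoothedStates
from pierisflight.stereo import (
    CameraModel,
    PixelTrack2D,
    Trajectory3D,
    WandObservation,
)

TRACK_COLUMNS = ["frame", "x_px", "y_px"]
WAND_COLUMNS = ["frame", "c1_ax_px", "c1_ay_px", "c1_bx_px", "c1_by_px",
                "c2_ax_px", "c2_ay_px", "c2_bx_px", "c2_by_px"]
SMOOTHED_COLUMNS = ["frame", "x", "y", "z", "vx", "vy", "vz",
                    "ax", "ay", "az", "estimated"]
TRAJECTORY_COLUMNS = ["frame", "x", "y", "z", "valid"]
LANDMARK_COLUMNS = ["specimen_id", "landmark_id", "x_mm", "y_mm"]
OUTLINE_COLUMNS = ["specimen_id", "wing", "vertex_index", "x_mm", "y_mm"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str],
                     path: str | Path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric value in column {c!r} "
                f"(first at row {int(bad.idxmax())})")


# ---------------------------------------------------------------------------
# pixel tracks and wand observations
# ---------------------------------------------------------------------------

def read_track_csv(path: str | Path, camera_id: str = "cam") -> PixelTrack2D:
    """Read a per-camera pixel track; blank cells mean not digitized."""
    df = _read_csv(path, TRACK_COLUMNS)
    _require_numeric(df, TRACK_COLUMNS, path)
    frames = df["frame"].to_numpy(dtype=float)
    if np.any(~np.isfinite(frames)):
        raise SchemaError(f"{path}: blank frame index")
    if len(frames) > 1 and np.any(np.diff(frames) <= 0):
        raise SchemaError(f"{path}: frame index not strictly increasing")
    xy = df[["x_px", "y_px"]].to_numpy(dtype=float)
    valid = np.isfinite(xy).all(axis=1)
    xy[~valid] = np.nan
    return PixelTrack2D(camera_id=camera_id,
                        frame_index=frames.astype(int),
                        xy=xy, valid=valid)


def write_track_csv(track: PixelTrack2D, path: str | Path) -> None:
    df = pd.DataFrame({"frame": track.frame_index,
                       "x_px": track.xy[:, 0], "y_px": track.xy[:, 1]})
    df.loc[~track.valid, ["x_px", "y_px"]] = np.nan
    df.to_csv(path, index=False)


def read_wand_csv(path: str | Path, wand_length: float = 0.24,
                  image_width: int = 2560,
                  image_height: int = 1440) -> WandObservation:
    """Read paired two-camera wand-endpoint pixels."""
    df = _read_csv(path, WAND_COLUMNS)
    _require_numeric(df, WAND_COLUMNS, path)
    n = len(df)
    pix = np.empty((n, 2, 2, 2))
    for ci, cam in enumerate(("c1", "c2")):
        for ei, end in enumerate(("a", "b")):
            pix[:, ci, ei, 0] = df[f"{cam}_{end}x_px"]
            pix[:, ci, ei, 1] = df[f"{cam}_{end}y_px"]
    return WandObservation(pixels=pix, wand_length=wand_length,
                           image_width=image_width,
                           image_height=image_height)


def write_wand_csv(obs: WandObservation, path: str | Path) -> None:
    data = {"frame": np.arange(len(obs.pixels))}
    for ci, cam in enumerate(("c1", "c2")):
        for ei, end in enumerate(("a", "b")):
            data[f"{cam}_{end}x_px"] = obs.pixels[:, ci, ei, 0]
            data[f"{cam}_{end}y_px"] = obs.pixels[:, ci, ei, 1]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration files
# ---------------------------------------------------------------------------

def write_calibration(cameras: tuple[CameraModel, ...],
                      path: str | Path) -> None:
    """Plain-text calibration: one block of 11 DLT coefficients + k1
    per camera."""
    lines = []
    for cam in cameras:
        lines.append(f"camera: {cam.id}")
        lines.append(f"image_size: {cam.image_width} {cam.image_height}")
        for j, L in enumerate(cam.dlt, start=1):
            lines.append(f"L{j}: {float(L)!r}")
        lines.append(f"k1: {float(cam.k1)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_calibration(path: str | Path) -> tuple[CameraModel, ...]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    cams = []
    block: dict[str, str] = {}

    def flush():
        if not block:
            return
        try:
            dlt = np.array([float(block[f"L{j}"]) for j in range(1, 12)])
            w, h = (int(v) for v in block["image_size"].split())
            cams.append(CameraModel(dlt=dlt, k1=float(block["k1"]),
                                    image_width=w, image_height=h,
                                    id=block["camera"]))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed calibration block "
                              f"({exc})") from exc
        block.clear()

    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            flush()
            continue
        if ":" not in line:
            raise SchemaError(f"{path}: malformed line {line!r}")
        k, v = line.split(":", 1)
        block[k.strip()] = v.strip()
    flush()
    if not cams:
        raise SchemaError(f"{path}: no camera blocks found")
    return tuple(cams)


# ---------------------------------------------------------------------------
# trajectories and smoothed states
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory3D, path: str | Path) -> None:
    pd.DataFrame({"frame": traj.frame_index,
                  "x": traj.xyz[:, 0], "y": traj.xyz[:, 1],
                  "z": traj.xyz[:, 2],
                  "valid": traj.valid.astype(int)}).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path,
                        dt: float = 1.0 / 120.0) -> Trajectory3D:
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    _require_numeric(df, TRAJECTORY_COLUMNS, path)
    return Trajectory3D(frame_index=df["frame"].to_numpy(dtype=int),
                        xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
                        valid=df["valid"].to_numpy(dtype=bool), dt=dt)


def write_smoothed_csv(states: SmoothedStates, path: str | Path) -> None:
    states.to_dataframe().to_csv(path, index=False)


def read_smoothed_csv(path: str | Path,
                      dt: float = 1.0 / 120.0) -> SmoothedStates:
    df = _read_csv(path, SMOOTHED_COLUMNS)
    _require_numeric(df, SMOOTHED_COLUMNS, path)
    return SmoothedStates(
        frame_index=df["frame"].to_numpy(dtype=int),
        position=df[["x", "y", "z"]].to_numpy(dtype=float),
        velocity=df[["vx", "vy", "vz"]].to_numpy(dtype=float),
        acceleration=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        estimated=df["estimated"].to_numpy(dtype=bool), dt=dt)


# ---------------------------------------------------------------------------
# landmarks and outlines
# ---------------------------------------------------------------------------

def write_landmark_csv(specimens: list[WingLandmarks],
                       path: str | Path) -> None:
    rows = []
    for lm in specimens:
        for j in range(N_LANDMARKS):
            rows.append({"specimen_id": lm.specimen_id,
                         "landmark_id": j + 1,
                         "x_mm": lm.landmarks[j, 0],
                         "y_mm": lm.landmarks[j, 1]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_outline_csv(specimens: list[WingLandmarks],
                      path: str | Path) -> None:
    rows = []
    for lm in specimens:
        for wing, outline in (("forewing", lm.forewing_outline),
                              ("hindwing", lm.hindwing_outline)):
            for j, (x, y) in enumerate(outline):
                rows.append({"specimen_id": lm.specimen_id, "wing": wing,
                             "vertex_index": j, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_thorax_csv(specimens: list[WingLandmarks],
                     path: str | Path) -> None:
    pd.DataFrame([{"specimen_id": lm.specimen_id,
                   "thorax_length_mm": lm.thorax_length_mm,
                   "thorax_width_mm": lm.thorax_width_mm}
                  for lm in specimens]).to_csv(path, index=False)


def read_landmark_specimens(landmark_path: str | Path,
                            outline_path: str | Path,
                            thorax_path: str | Path,
                            ) -> list[WingLandmarks]:
    """Reassemble WingLandmarks objects from the three morphology CSVs."""
    lm_df = _read_csv(landmark_path, LANDMARK_COLUMNS)
    ol_df = _read_csv(outline_path, OUTLINE_COLUMNS)
    th_df = _read_csv(thorax_path, ["specimen_id", "thorax_length_mm",
                                    "thorax_width_mm"])
    bad = ~lm_df["landmark_id"].isin(range(1, N_LANDMARKS + 1))
    if bad.any():
        raise SchemaError(f"{landmark_path}: landmark_id outside 1..19")
    th = th_df.set_index("specimen_id")
    specimens = []
    for sid, grp in lm_df.groupby("specimen_id", sort=False):
        lms = np.full((N_LANDMARKS, 2), np.nan)
        idx = grp["landmark_id"].to_numpy(dtype=int) - 1
        lms[idx] = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        ols = ol_df[ol_df.specimen_id == sid]
        fw = ols[ols.wing == "forewing"].sort_values("vertex_index")
        hw = ols[ols.wing == "hindwing"].sort_values("vertex_index")
        if fw.empty or hw.empty:
            raise SchemaError(f"{outline_path}: specimen {sid} lacks "
                              "forewing or hindwing outline")
        if sid not in th.index:
            raise SchemaError(f"{thorax_path}: specimen {sid} missing")
        specimens.append(WingLandmarks(
            specimen_id=str(sid), landmarks=lms,
            forewing_outline=fw[["x_mm", "y_mm"]].to_numpy(dtype=float),
            hindwing_outline=hw[["x_mm", "y_mm"]].to_numpy(dtype=float),
            thorax_length_mm=float(th.loc[sid, "thorax_length_mm"]),
            thorax_width_mm=float(th.loc[sid, "thorax_width_mm"])))
    return specimens


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

MAX_PLAUSIBLE_SPEED = 20.0  # m/s


def validate_io(files: dict[str, str | Path]) -> dict:
    """Schema and sanity checks over a bundle of pipeline files.

    ``files`` maps a kind ('track', 'wand', 'calibration', 'trajectory',
    'smoothed', 'flights') to a path.  Returns a report dict with
    per-file row counts and a (possibly empty) list of failures; never
    raises for content problems.
    """
    failures: list[str] = []
    counts: dict[str, int] = {}
    for kind, path in files.items():
        kind = kind.split(":", 1)[0]  # allow 'track:<path>' disambiguation
        path = Path(path)
        try:
            if kind == "track":
                df = _read_csv(path, TRACK_COLUMNS)
                _require_numeric(df, TRACK_COLUMNS, path)
                if len(df) > 1 and (df["frame"].diff()[1:] <= 0).any():
                    failures.append(f"{path}: non-monotone frame index")
                for c in ("x_px", "y_px"):
                    if (df[c] > 2560).any() or (df[c] < 0).any():
                        failures.append(
                            f"{path}: column {c} outside sensor range")
            elif kind == "wand":
                df = _read_csv(path, WAND_COLUMNS)
                _require_numeric(df, WAND_COLUMNS, path)
            elif kind == "calibration":
                read_calibration(path)
                df = None
            elif kind == "trajectory":
                df = _read_csv(path, TRAJECTORY_COLUMNS)
            elif kind == "smoothed":
                df = _read_csv(path, SMOOTHED_COLUMNS)
                speed = np.linalg.norm(
                    df[["vx", "vy", "vz"]].to_numpy(dtype=float), axis=1)
                if (speed > MAX_PLAUSIBLE_SPEED).any():
                    failures.append(
                        f"{path}: speed exceeds {MAX_PLAUSIBLE_SPEED} m/s")
                if len(df) > 1 and (df["frame"].diff()[1:] <= 0).any():
                    failures.append(f"{path}: non-monotone frame index")
            elif kind == "flights":
                df = _read_csv(path, ["trajectory_id", "mean_velocity"])
                if (df["mean_velocity"] > MAX_PLAUSIBLE_SPEED).any():
                    failures.append(
                        f"{path}: mean_velocity exceeds "
                        f"{MAX_PLAUSIBLE_SPEED} m/s")
            else:
                failures.append(f"{path}: unknown file kind {kind!r}")
                df = None
            if df is not None:
                counts[str(path)] = len(df)
        except SchemaError as exc:
            failures.append(str(exc))
    return {"failures": failures, "counts": counts,
            "ok": not failures}
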