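"""End-to-end pipeline: simulate -> calibrate -> triangulate -> smooth
-> kinematics -> morpho -> stats.

Each stage reads and writes the documented CSV dialects inside one
output directory, so any contiguous subrange of stages can be re-run
from files on disk.  A manifest (JSON) records the full configuration,
derived seeds, library versions and per-stage record counts; identical
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pierisflight import io as pfio
from pierisflight.exceptions import (
    EmptyTrackError,
    InsufficientDataError,
    PierisFlightError,
    SchemaError,
)
from pierisflight.kinematics import WingbeatRecord, summarize_flight
from pierisflight.morphometrics import summarize_morphology
from pierisflight.smoothing import kalman_smooth
from pierisflight.stereo import triangulate, wand_calibrate
from pierisflight.synthetic import (
    CohortConfig,
    SceneConfig,
    generate_cohort,
    generate_wand_sweep,
    render_pixel_tracks,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "triangulate", "smooth",
          "kinematics", "morpho", "stats")


@dataclass
class RunConfig:
    """Complete, serializable configuration of a pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        pixel_noise_px=0.5, dropout=0.02))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    wand_poses: int = 150
    wand_length: float = 0.24
    smoothing_q: float | None = None
    smoothing_r: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.seed < 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")

    def derived_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the run seed."""
        return int(np.random.SeedSequence(
            [self.seed, STAGES.index(stage)]).generate_state(1)[0] % 2 ** 31)

    def to_dict(self) -> dict:
        d = asdict(self)
        # dict keys that are tuples do not survive JSON/YAML round trips
        d["cohort"]["n_per_group"] = {
            "|".join(k): v for k, v in d["cohort"]["n_per_group"].items()}
        d["cohort"]["tracks_per_cell"] = {
            "|".join(k): v for k, v in d["cohort"]["tracks_per_cell"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = SceneConfig(**d.pop("scene", {}))
        cd = dict(d.pop("cohort", {}))
        if "n_per_group" in cd:
            cd["n_per_group"] = {tuple(k.split("|")): v
                                 for k, v in cd["n_per_group"].items()}
        if "tracks_per_cell" in cd:
            cd["tracks_per_cell"] = {tuple(k.split("|")): v
                                     for k, v in cd["tracks_per_cell"].items()}
        if "temperature_range" in cd and cd["temperature_range"] is not None:
            cd["temperature_range"] = tuple(cd["temperature_range"])
        if "cage" in cd:  # guard against misplaced keys
            raise SchemaError("'cage' belongs to the scene block")
        cohort = CohortConfig(**cd)
        return cls(scene=scene, cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        try:
            raw = yaml.safe_load(Path(path).read_text())
        except Exception as exc:
            raise SchemaError(f"{path}: unreadable config ({exc})") from exc
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        # listy YAML scalars back to tuples where dataclasses expect them
        for blk, key in (("scene", "cage"),):
            if blk in raw and key in raw[blk]:
                raw[blk][key] = tuple(raw[blk][key])
        try:
            return cls.from_dict(raw)
        except TypeError as exc:
            raise SchemaError(f"{path}: unknown config key ({exc})") from exc

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))


def demo_config(out_dir: str = "demo_run", seed: int = 7) -> RunConfig:
    """A reduced cohort that completes end-to-end in well under 5 min."""
    cohort = CohortConfig(
        n_per_group={("P. napi", "spring", "male"): 2,
                     ("P. napi", "summer", "male"): 3,
                     ("P. rapae", "spring", "male"): 2,
                     ("P. rapae", "summer", "male"): 3},
        tracks_per_cell={("spring", "male"): 8, ("summer", "male"): 12},
        n_missing_wingbeats=1)
    return RunConfig(out_dir=out_dir, seed=seed, cohort=cohort,
                     wand_poses=120)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise SchemaError(
            f"missing input file: {path} (run the earlier stage first)")
    return path


def stage_simulate(config: RunConfig) -> dict:
    out = _outdir(config)
    obs = generate_wand_sweep(config.scene, config.wand_length,
                              n_poses=config.wand_poses,
                              seed=config.derived_seed("simulate"))
    pfio.write_wand_csv(obs, out / "wand.csv")
    cohort = generate_cohort(config.cohort,
                             seed=config.derived_seed("simulate"),
                             realize_paths=True)
    (out / "tracks").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.derived_seed("simulate") + 1)
    kept = []
    for tid, (traj, _truth) in cohort.trajectories.items():
        try:
            t1, t2 = render_pixel_tracks(traj, config.scene,
                                         seed=int(rng.integers(2 ** 31)))
        except EmptyTrackError:
            logger.warning("trajectory %s never visible; skipped", tid)
            continue
        pfio.write_track_csv(t1, out / "tracks" / f"{tid}_cam1.csv")
        pfio.write_track_csv(t2, out / "tracks" / f"{tid}_cam2.csv")
        kept.append(tid)
    info = cohort.flights[cohort.flights.trajectory_id.isin(kept)]
    info.to_csv(out / "trajectory_info.csv", index=False)
    wb = cohort.wingbeats[cohort.wingbeats.trajectory_id.isin(kept)]
    wb.to_csv(out / "wingbeats.csv", index=False)
    pfio.write_landmark_csv(cohort.landmarks, out / "landmarks.csv")
    pfio.write_outline_csv(cohort.landmarks, out / "outlines.csv")
    pfio.write_thorax_csv(cohort.landmarks, out / "thorax.csv")
    cohort.specimens.to_csv(out / "specimens.csv", index=False)
    return {"trajectories": len(kept), "wand_poses": config.wand_poses,
            "specimens": len(cohort.specimens)}


def stage_calibrate(config: RunConfig) -> dict:
    out = _outdir(config)
    obs = pfio.read_wand_csv(_require(out / "wand.csv"),
                             wand_length=config.wand_length,
                             image_width=config.scene.image_width,
                             image_height=config.scene.image_height)
    result = wand_calibrate(obs)
    pfio.write_calibration(result.cameras, out / "calibration.txt")
    (out / "calibration_report.txt").write_text(result.summary() + "\n")
    return {"wand_frames": result.n_frames,
            "mean_wand_length_cm": float(result.mean_wand_length * 100.0),
            "rms_reprojection_px": float(result.rms_reprojection_px)}


def stage_triangulate(config: RunConfig) -> dict:
    out = _outdir(config)
    cams = pfio.read_calibration(_require(out / "calibration.txt"))
    info = pd.read_csv(_require(out / "trajectory_info.csv"))
    (out / "trajectories").mkdir(exist_ok=True)
    n = 0
    for tid in info.trajectory_id:
        t1 = pfio.read_track_csv(
            _require(out / "tracks" / f"{tid}_cam1.csv"), "cam1")
        t2 = pfio.read_track_csv(
            _require(out / "tracks" / f"{tid}_cam2.csv"), "cam2")
        traj = triangulate(t1, t2, (cams[0], cams[1]), dt=config.scene.dt)
        pfio.write_trajectory_csv(traj, out / "trajectories" / f"{tid}.csv")
        n += 1
    return {"trajectories": n}


def stage_smooth(config: RunConfig) -> dict:
    out = _outdir(config)
    info = pd.read_csv(_require(out / "trajectory_info.csv"))
    (out / "smoothed").mkdir(exist_ok=True)
    n, skipped = 0, []
    for tid in info.trajectory_id:
        traj = pfio.read_trajectory_csv(
            _require(out / "trajectories" / f"{tid}.csv"),
            dt=config.scene.dt)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states = kalman_smooth(traj, q=config.smoothing_q,
                                       r=config.smoothing_r)
        except (InsufficientDataError, PierisFlightError):
            logger.warning("trajectory %s unsmoothable; skipped", tid)
            skipped.append(tid)
            continue
        pfio.write_smoothed_csv(states, out / "smoothed" / f"{tid}.csv")
        n += 1
    return {"smoothed": n, "skipped": skipped}


def stage_kinematics(config: RunConfig) -> dict:
    out = _outdir(config)
    info = pd.read_csv(_require(out / "trajectory_info.csv"))
    wb = pd.read_csv(_require(out / "wingbeats.csv")).set_index(
        "trajectory_id")
    rows = []
    for _, meta in info.iterrows():
        tid = meta.trajectory_id
        path = out / "smoothed" / f"{tid}.csv"
        if not path.exists():
            continue
        states = pfio.read_smoothed_csv(path, dt=config.scene.dt)
        rec = None
        if tid in wb.index and np.isfinite(wb.loc[tid, "n_wingbeats"]):
            rec = WingbeatRecord(
                trajectory_id=tid,
                n_wingbeats=int(wb.loc[tid, "n_wingbeats"]),
                duration_s=float(wb.loc[tid, "duration_s"]))
        summ = summarize_flight(states, rec, trajectory_id=tid)
        row = summ.to_dict()
        for k in ("specimen_id", "species", "form", "sex", "day",
                  "temperature_c"):
            row[k] = meta[k]
        rows.append(row)
    flights = pd.DataFrame(rows)
    flights.to_csv(out / "flights.csv", index=False)
    return {"flights": len(flights)}


def stage_morpho(config: RunConfig) -> dict:
    out = _outdir(config)
    specimens = pfio.read_landmark_specimens(
        _require(out / "landmarks.csv"), _require(out / "outlines.csv"),
        _require(out / "thorax.csv"))
    spec_meta = pd.read_csv(_require(out / "specimens.csv")).set_index(
        "specimen_id")
    rows = []
    for lm in specimens:
        row = summarize_morphology(lm).to_dict()
        for k in ("species", "form", "sex"):
            row[k] = spec_meta.loc[lm.specimen_id, k]
        rows.append(row)
    morpho = pd.DataFrame(rows)
    morpho.to_csv(out / "morpho.csv", index=False)
    return {"specimens": len(morpho)}


def stage_stats(config: RunConfig) -> dict:
    from pierisflight import stats as pfstats

    out = _outdir(config)
    flights = pd.read_csv(_require(out / "flights.csv"))
    morpho = pd.read_csv(_require(out / "morpho.csv"))
    report: list[str] = []
    pfstats.pairwise_correlations(morpho).to_csv(
        out / "correlations.csv", index=False)
    pfstats.anova_morphology(morpho).to_csv(out / "anova.csv", index=False)

    model_rows, emmean_rows, effect_rows = [], [], []
    merged = flights.merge(
        morpho[["specimen_id", *pfstats.MORPHO_VARIABLES]], on="specimen_id")
    for resp in pfstats.FLIGHT_RESPONSES:
        if resp not in flights or flights[resp].notna().sum() < 10:
            report.append(f"{resp}: too few observations; skipped")
            continue
        try:
            res = pfstats.fit_flight_lmm(flights, resp)
        except (ValueError, np.linalg.LinAlgError) as exc:
            report.append(f"{resp}: model failed ({exc})")
            continue
        if res.fit.singular:
            report.append(f"{resp}: random-intercept variance at zero "
                          "boundary (OLS-like inference)")
        for fac in ("species", "form"):
            try:
                tt = pfstats.term_test(res, fac)
            except ValueError:
                continue
            model_rows.append({"response": resp, **tt,
                               "log_transformed": res.log_transformed})
        for fac in ("form",):
            try:
                mm = pfstats.marginal_means(
                    res, fac, backtransform=res.log_transformed)
            except ValueError:
                continue
            for _, r in mm.means.iterrows():
                emmean_rows.append({"response": resp, "factor": fac,
                                    **r.to_dict()})
        try:
            _, eff = pfstats.morphology_effects(merged, resp)
            effect_rows.extend(eff.to_dict("records"))
        except (ValueError, np.linalg.LinAlgError) as exc:
            report.append(f"{resp}: morphology model failed ({exc})")
    pd.DataFrame(model_rows).to_csv(out / "flight_models.csv", index=False)
    pd.DataFrame(emmean_rows).to_csv(out / "emmeans.csv", index=False)
    pd.DataFrame(effect_rows).to_csv(
        out / "morphology_effects.csv", index=False)
    (out / "stats_report.txt").write_text(
        "\n".join(report) + ("\n" if report else ""))
    return {"responses_modelled": len({r['response'] for r in model_rows}),
            "warnings": len(report)}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "calibrate": stage_calibrate,
    "triangulate": stage_triangulate, "smooth": stage_smooth,
    "kinematics": stage_kinematics, "morpho": stage_morpho,
    "stats": stage_stats,
}


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] | None = None) -> dict:
    """Run a contiguous subrange of pipeline stages and write a manifest.

    Returns the manifest dict (also written to ``<out>/manifest.json``).
    """
    stages = tuple(stages) if stages else STAGES
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    idx = [STAGES.index(s) for s in stages]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError("stages must form a contiguous pipeline subrange")
    out = _outdir(config)
    counts = {}
    for s in stages:
        logger.info("stage %s", s)
        counts[s] = _STAGE_FUNCS[s](config)
    import pierisflight
    import scipy

    manifest = {
        "config": config.to_dict(),
        "stages": list(stages),
        "derived_seeds": {s: config.derived_seed(s) for s in stages},
        "versions": {"pierisflight": pierisflight.__version__,
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "stage_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest
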