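"""Synthetic generators: determinism, composition, ground-truth
consistency."""

import numpy as np
import pytest
from scipy import stats as sps

from pierisflight.exceptions import GenerationError, InsufficientDataError
from pierisflight.kinematics import summarize_flight
from pierisflight.smoothing import SmoothedStates
from pierisflight.stereo import triangulate_points
from pierisflight.synthetic import (
    CohortConfig,
    PathProfile,
    SceneConfig,
    generate_cohort,
    generate_flight_path,
    generate_wand_sweep,
    generate_wing_landmarks,
    render_pixel_tracks,
)


class TestPaths:
    def test_circle_truth(self):
        p = PathProfile(kind="circle", speed=1.0, radius=0.5, duration=3.0)
        _, truth = generate_flight_path(p)
        assert truth.flight_curvature == pytest.approx(2.0, rel=1e-6)
        assert truth.turning_rate == pytest.approx(2.0, rel=1e-4)
        assert truth.turning_acceleration == pytest.approx(2.0, rel=1e-6)

    def test_straight_truth(self):
        p = PathProfile(kind="straight", speed=1.2, duration=2.0)
        _, truth = generate_flight_path(p)
        assert truth.flight_curvature == pytest.approx(0.0, abs=1e-9)
        assert truth.sinuosity == pytest.approx(1.0)

    def test_semicircle_sinuosity(self):
        p = PathProfile(kind="semicircle", speed=1.0, radius=0.6)
        _, truth = generate_flight_path(p)
        assert truth.sinuosity == pytest.approx(2 / np.pi, rel=5e-3)

    def test_crw_deterministic(self):
        p = PathProfile(kind="crw", speed=1.0, duration=2.0, seed=9)
        t1, _ = generate_flight_path(p)
        t2, _ = generate_flight_path(p)
        np.testing.assert_array_equal(t1.xyz, t2.xyz)

    def test_cage_exit_truncated(self):
        p = PathProfile(kind="straight", speed=3.0, duration=3.0,
                        start=(1.0, 1.25, 1.2))
        with pytest.warns(UserWarning):
            traj, _ = generate_flight_path(p, scene=SceneConfig())
        assert not traj.valid.all()

    def test_too_short_profile(self):
        with pytest.raises(ValueError):
            PathProfile(kind="straight", duration=0.1)

    def test_negative_speed(self):
        with pytest.raises(GenerationError):
            PathProfile(kind="straight", speed=-1.0)


class TestRendering:
    def test_noiseless_round_trip(self, scene):
        p = PathProfile(kind="helix", speed=1.2, radius=0.4, duration=2.0,
                        start=(3.0, 1.25, 1.2))
        traj, _ = generate_flight_path(p)
        t1, t2 = render_pixel_tracks(traj, scene, seed=0)
        cams = scene.cameras()
        both = t1.valid & t2.valid
        rec, ok = triangulate_points(t1.xy[both], t2.xy[both],
                                     cams[0], cams[1])
        assert np.max(np.abs(rec[ok] - traj.xyz[both][ok])) < 1e-9

    def test_dropout_binomial(self):
        scene = SceneConfig(dropout=0.05)
        p = PathProfile(kind="straight", speed=0.5, duration=3.0,
                        start=(2.0, 1.25, 1.2))
        traj, _ = generate_flight_path(p)
        n = len(traj.frame_index)
        t1, _ = render_pixel_tracks(traj, scene, seed=4)
        dropped = n - t1.n_valid
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= dropped <= hi

    def test_deterministic(self, noisy_scene):
        p = PathProfile(kind="circle", speed=1.0, radius=0.5, duration=2.0)
        traj, _ = generate_flight_path(p)
        a, _ = render_pixel_tracks(traj, noisy_scene, seed=3)
        b, _ = render_pixel_tracks(traj, noisy_scene, seed=3)
        np.testing.assert_array_equal(a.xy, b.xy)


class TestWandSweep:
    def test_exact_separation_and_default_length(self, scene):
        obs = generate_wand_sweep(scene, n_poses=40, seed=1)
        assert obs.wand_length == 0.24
        assert obs.n_usable == 40

    def test_min_poses(self, scene):
        with pytest.raises(InsufficientDataError):
            generate_wand_sweep(scene, n_poses=10)

    def test_oversize_wand(self, scene):
        with pytest.raises(GenerationError):
            generate_wand_sweep(scene, wand_length=3.0)

    def test_same_seed_identical(self, scene):
        a = generate_wand_sweep(scene, n_poses=35, seed=8)
        b = generate_wand_sweep(scene, n_poses=35, seed=8)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestWingGenerator:
    def test_zero_variance_identical(self):
        a = generate_wing_landmarks("P. napi", "summer", seed=1,
                                    zero_variance=True)
        b = generate_wing_landmarks("P. napi", "summer", seed=99,
                                    zero_variance=True)
        np.testing.assert_allclose(a.landmarks, b.landmarks)

    def test_unknown_group(self):
        with pytest.raises(GenerationError):
            generate_wing_landmarks("P. napi", "winter")
        with pytest.raises(GenerationError):
            generate_wing_landmarks("P. brassicae", "spring")

    def test_infeasible_explicit_target(self):
        with pytest.raises(GenerationError):
            generate_wing_landmarks(
                "P. napi", "spring", zero_variance=True,
                form_params={"spring": {
                    "forewing_area_mm2": (225.6, 0.0),
                    "aspect_ratio": (1.77, 0.0),
                    "outer_edge_index": (0.5, 0.0),  # < 1: impossible
                    "wing_loading_mm": (0.0249, 0.0)}})


class TestCohort:
    def test_study_composition(self, cohort):
        assert len(cohort.specimens) == 31
        assert len(cohort.flights) == 106
        forms = cohort.flights.form.value_counts()
        assert forms["spring"] == 26 and forms["summer"] == 80
        per_ind = cohort.flights.groupby("specimen_id").size()
        assert per_ind.between(1, 6).all()

    def test_missing_wingbeats(self, cohort):
        assert cohort.flights.wingbeat_frequency.isna().sum() == 4
        assert cohort.flights.advance_ratio.isna().sum() == 4

    def test_deterministic(self):
        a = generate_cohort(seed=3)
        b = generate_cohort(seed=3)
        assert a.flights.equals(b.flights)

    def test_null_cohort_shares_means(self):
        cfg = CohortConfig(sigma_individual=0.0, sigma_residual=0.0)
        coh = generate_cohort(cfg, seed=0, form_effect=False)
        v = coh.flights.groupby("form").mean_velocity.mean()
        assert v["spring"] == pytest.approx(v["summer"], rel=1e-12)

    def test_zero_individual_sd_shares_group_mean(self):
        cfg = CohortConfig(sigma_individual=0.0, sigma_residual=0.0)
        coh = generate_cohort(cfg, seed=0)
        per_track = coh.flights.groupby("form").mean_velocity.nunique()
        assert (per_track == 1).all()

    def test_large_group_mean_velocity(self):
        cfg = CohortConfig(
            n_per_group={("P. napi", "spring", "male"): 60,
                         ("P. napi", "summer", "male"): 60},
            tracks_per_cell={("spring", "male"): 240,
                             ("summer", "male"): 240},
            n_missing_wingbeats=0)
        coh = generate_cohort(cfg, seed=12)
        m = coh.flights.groupby("form").mean_velocity.mean()
        # lognormal mean exp(mu + s^2/2): medians centre on the targets
        med = coh.flights.groupby("form").mean_velocity.median()
        assert med["spring"] == pytest.approx(1.2, rel=0.1)
        assert med["summer"] == pytest.approx(1.7, rel=0.1)
        assert m["summer"] > m["spring"]

    def test_track_allocation_infeasible(self):
        cfg = CohortConfig(
            n_per_group={("P. napi", "spring", "male"): 2},
            tracks_per_cell={("spring", "male"): 40})
        with pytest.raises(GenerationError):
            generate_cohort(cfg, seed=0)

    def test_realized_paths_match_targets(self):
        cfg = CohortConfig(
            n_per_group={("P. napi", "summer", "male"): 2},
            tracks_per_cell={("summer", "male"): 4},
            n_missing_wingbeats=0)
        coh = generate_cohort(cfg, seed=5, realize_paths=True)
        for _, row in coh.flights.iterrows():
            _, truth = coh.trajectories[row.trajectory_id]
            assert truth.mean_velocity == pytest.approx(row.mean_velocity,
                                                        rel=1e-6)
            assert truth.flight_curvature == pytest.approx(
                row.flight_curvature, rel=1e-6)

    def test_temperature_range_and_mean(self):
        cfg = CohortConfig(
            n_per_group={("P. napi", "summer", "male"): 40},
            tracks_per_cell={("summer", "male"): 160},
            n_missing_wingbeats=0)
        coh = generate_cohort(cfg, seed=2)
        t = coh.flights.temperature_c
        assert t.between(10, 40).all()

    def test_morpho_correlation_recovered(self):
        from pierisflight.morphometrics import summarize_morphology

        vals = [summarize_morphology(
            generate_wing_landmarks("P. rapae", "spring", seed=s))
            for s in range(400)]
        r = np.corrcoef([v.forewing_area_cm2 for v in vals],
                        [v.aspect_ratio for v in vals])[0, 1]
        # configured cohort correlation -0.4012; truncation attenuates
        assert -0.55 < r < -0.25


class TestCrossModuleConsistency:
    def test_truth_matches_kinematics_on_noiseless_path(self):
        p = PathProfile(kind="helix", speed=1.4, radius=0.45, pitch=0.12,
                        duration=3.0)
        traj, truth = generate_flight_path(p)
        # numerically differentiate the noiseless trajectory
        vel = np.gradient(traj.xyz, p.dt, axis=0)
        acc = np.gradient(vel, p.dt, axis=0)
        states = SmoothedStates(frame_index=traj.frame_index,
                                position=traj.xyz, velocity=vel,
                                acceleration=acc,
                                estimated=np.zeros(len(vel), bool),
                                dt=p.dt)
        numeric = summarize_flight(states, burn_in=8)
        assert numeric.mean_velocity == pytest.approx(truth.mean_velocity,
                                                      rel=0.01)
        assert numeric.flight_curvature == pytest.approx(
            truth.flight_curvature, rel=0.01)
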