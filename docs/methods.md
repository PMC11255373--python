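# Methods

This document records the measurement model, the synthetic-data design,
the statistical machinery and the numerical conventions implemented in
`pierisflight`, together with the assumptions behind them and their
known limitations.

## 1. Camera model and calibration

### 1.1 DLT camera

Each camera is an 11-coefficient direct linear transformation (DLT):
world point **X** (metres) maps to pixel coordinates

```
u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)
```

optionally followed by a one-parameter radial distortion about the
geometric image centre **c**:

```
x_d = c + (x_u − c)(1 + k1 r²),    r = |x_u − c| / R
```

with `R` the half image diagonal, so `k1` is dimensionless and O(1)
values are meaningful across resolutions. Undistortion inverts this map
by fixed-point iteration (tolerance 1e-8 px); non-contracting `k1`
raises an invertibility error rather than returning garbage.

`dlt_calibrate` solves the standard linear system from ≥ 6 non-coplanar
world/pixel correspondences and reports the per-coordinate RMS
reprojection residual, which for i.i.d. pixel noise of standard
deviation σ estimates σ itself.

### 1.2 Wand-based stereo self-calibration

Field calibration uses a rigid two-point wand of known length L = 0.24 m
waved through the volume. `wand_calibrate`:

1. builds point correspondences from the wand endpoints in both views;
2. estimates an essential matrix by the normalized 8-point algorithm
   under a small set of focal-length guesses (0.25, 0.5, 1.0 × image
   width) and recovers the relative pose with the cheirality test;
3. scales the reconstruction so the mean triangulated endpoint
   separation equals L;
4. refines focal lengths, pose and structure by bundle adjustment in
   which every frame contributes reprojection residuals plus a
   wand-length residual with σ_len = 1e-3·L, selecting the solution
   with the best final cost;
5. fixes the gauge: world origin beneath the wand cloud's centroid,
   z vertical.

Diagnostics (mean/SD of re-triangulated wand lengths, reprojection RMS)
come from an independent re-triangulation with the final cameras, so
they are honest measures rather than echoes of the optimizer's own
residuals. At 0.5 px noise and 200 poses the reconstructed wand length
is within a fraction of a percent of truth.

### 1.3 Triangulation

Two-view triangulation solves the linear DLT system per frame after
undistortion and flags frames seen by fewer than two cameras as
invalid; those remain in the output with NaN coordinates so that the
frame clock stays intact.

## 2. Trajectory smoothing

Raw triangulated tracks are smoothed with a linear-Gaussian state-space
model: state = (position, velocity, acceleration) per axis, white-jerk
process noise of spectral density q (default 1.0 m²/s⁵) and i.i.d.
measurement noise r (default 2.5e-5 m², i.e. ≈ 5 mm at the working
geometry). A Kalman filter handles missing observations by pure
prediction, and a Rauch–Tung–Striebel pass smooths backwards. Gap
frames are flagged `estimated`.

Choices worth noting:

- The track is trimmed to its observed span (first to last valid frame)
  before filtering. A constant-acceleration model extrapolated over a
  long invalid tail coasts quadratically and corrupts every summary
  statistic; no-extrapolation is the safer contract.
- `tune_noise` selects (q, r) on a fixed 5 × 5 log grid centred on a
  pilot estimate by one-step predictive likelihood. The grid is coarse
  by design: it is deterministic, cheap, and accurate to within a grid
  step, which is all downstream summaries need.
- At least 10 valid frames are required; fewer raises an error rather
  than returning a degenerate fit.

## 3. Flight kinematics

Eleven per-trajectory parameters are computed from the smoothed states,
skipping a 5-frame burn-in at each end (filter start-up transient)
unless the track is too short to afford it:

- covered distance: sum of displacement norms;
- mean velocity, mean acceleration: means of |v| and |a|;
- flight height: mean z;
- ascent angle: mean signed angle of the velocity vector to the
  horizontal plane, in degrees (descent negative; an absolute variant
  averages magnitudes);
- sinuosity: net displacement / covered distance ∈ [0, 1]
  (a semicircle gives 2/π);
- flight curvature: mean of κ = |v × a| / |v|³;
- turning rate: mean angular change of successive velocity directions
  per unit time (rad/s; for a circle, v/r);
- turning acceleration: mean |v × a| / |v|, the magnitude of the
  velocity-normal acceleration component (for a circle, v²/r);
- wingbeat frequency: counted wingbeats / duration (from a per-track
  wingbeat record; NaN when not counted);
- advance ratio: mean velocity / wingbeat frequency, i.e. metres
  advanced per wingbeat; NaN when frequency is missing.

All quantities are invariant to rigid motions of the world frame and
transform with the expected powers under spatial and temporal
rescaling; the test suite asserts these equivariances exactly.

## 4. Wing morphometrics

Specimens are 19-landmark configurations (mm) plus forewing/hindwing
outline polygons and thorax calliper measurements:

- forewing length: landmark 1 (base) to 13 (apex), reported in cm;
- forewing width: maximum outline extent perpendicular to the
  length axis;
- aspect ratio: length / width;
- areas: Gauss shoelace over the outline polygons (validated as simple
  polygons via `shapely`; self-intersection raises);
- thoracic volume: cylinder π·(W/2)²·L with the calliper width treated
  as diameter;
- wing loading: thoracic volume / total wing area (both cm- and
  mm-based variants);
- outer-edge index: polyline length of landmarks 13–19 divided by the
  chord 13–19 (≥ 1 by the triangle inequality; 1 iff collinear);
- marginal-region index: straight distance 1–9 divided by the straight
  distance 1–13.

## 5. Synthetic ground truth

There is no bundled video or field data; every number the pipeline
consumes is generated with known truth.

### 5.1 Scene and paths

`SceneConfig` models a 6 × 2.5 × 2.5 m cage filmed by two perpendicular
2560 × 1440 cameras at 120 fps. Analytic path families
(straight, circle, semicircle, helix, correlated random walk) come with
closed-form kinematic truths computed from the exact state sequence
(no estimation burn-in, since analytic states have no transient).
`render_pixel_tracks` projects a path through both cameras, applies
Gaussian pixel noise and Bernoulli dropout, and marks frames outside
either sensor as missing; paths leaving the cage are truncated with a
warning.

### 5.2 Cohorts

`generate_cohort` reproduces the study design as its default
configuration: 31 individuals across species × form × sex cells, 106
flight tracks (26 spring, 80 summer, 1–6 per individual), 16 recording
days with day-level ambient temperatures (14–36 °C), and 4 tracks
without wingbeat counts. Group-level flight-parameter means differ by
seasonal form (e.g. mean velocity 1.2 m/s spring vs 1.7 m/s summer) and
individual tracks are drawn log-normally around individual means:
between-individual SD 0.20 and residual SD 0.30 on the log scale,
calibrated so that the velocity form contrast has the same
standardized magnitude (t ≈ 3.3 at study sample sizes) as the
motivating analysis. `form_effect=False` produces null cohorts for
calibration of test size. With `realize_paths=True` each sampled
parameter row is realized as an actual helix whose speed, curvature and
covered distance match the row exactly; acceleration then follows the
identity |a| = v²κ rather than being independently settable — a
deliberate consequence of using smooth analytic paths.

Wing specimens are generated by deforming an elliptical template
(64-gon with vertices pinned on both axes) so that forewing area,
aspect ratio, outer-edge index, marginal-region index and wing loading
hit their drawn targets exactly (the edge index via 1-D root finding on
an edge-bulge parameter). Draws are truncated normals (resampled within
feasibility bounds: area > 50 mm², aspect > 1.02, edge ≥ 1), and area
and aspect ratio are drawn jointly with correlation −0.40 to mimic the
observed covariance of wing dimensions. Explicitly requested infeasible
targets (e.g. an edge index below 1 with zero variance) raise a
generation error instead of being silently clamped.

## 6. Statistics

### 6.1 Random-intercept mixed models

All comparative models are Gaussian random-intercept LMMs (individual
as the grouping factor). The implementation profiles the variance
ratio λ = σ_g²/σ_e²: at fixed λ the GLS estimates, residual quadratic
form and log-determinants are closed-form block computations
(Sherman–Morrison per group), so (RE)ML fitting is a bounded 1-D
optimization in log λ — fast, derivative-free and free of convergence
tuning. Near-zero σ_g² is flagged singular (inference degenerates to
OLS). Denominator degrees of freedom for t/F tests use the
Satterthwaite approximation with the variance-component covariance
taken from the numeric REML Hessian. The test suite cross-checks
coefficients, standard errors, variance components and ML likelihoods
against `statsmodels.MixedLM` (REML log-likelihood constants differ by
convention across packages, so the suite checks criterion maximization
rather than the constant).

Responses that are strictly positive are natural-log transformed by
default; sign-carrying responses (ascent angle) are analysed
untransformed. Log covered distance enters as a fixed covariate in the
flight models to absorb track-length effects.

### 6.2 Marginal means, contrasts, effect sizes

Estimated marginal means average the model prediction over a reference
grid: all factor-level combinations equally weighted, covariates at
their observed means. Pairwise contrasts use Tukey adjustment via the
studentized range distribution (p = P(Q ≥ |t|√2) with Satterthwaite
df). Back-transformed means report exp(mean) with delta-method SEs.
Cohen's d is the fitted coefficient divided by its standard error.

### 6.3 Selection and multivariate structure

Two selection flavours over the (log-transformed) morphological
predictors: stepwise backward elimination on Satterthwaite p-values
(α = 0.05), and all-subsets ML-AICc ranking with Akaike weights and
per-variable weight sums, capped at 12 candidate terms (4096 models).
PCA of the flight parameters handles missing wingbeat-derived cells by
EM-style alternation between a rank-k SVD reconstruction and
re-standardization (deterministic, tolerance 1e-8, ≤ 20% missingness
per column); with nothing missing it reduces exactly to plain PCA.
Pearson correlations and two-way (species × form, Type-II) ANOVAs over
the morphology table use `scipy`/`statsmodels`.

Multiple testing across response variables is deliberately not
adjusted, matching the analysis plan this layer mirrors; marginal
p-values should be read accordingly.

## 7. Reproducibility conventions

- Every stochastic routine takes an integer seed; cohort and pipeline
  seeds are constrained to [0, 2³¹).
- The pipeline derives one independent sub-seed per stage via
  `numpy.random.SeedSequence([run_seed, stage_index])`, so re-running a
  later stage never perturbs an earlier one.
- `manifest.json` records configuration, derived seeds, library
  versions and per-stage record counts; identical configuration and
  seed give byte-identical CSVs.
- All file formats are documented CSV dialects (plus a plain-text
  calibration format) with schema-validating readers that name the
  offending file and column.

## 8. Limitations

- The camera model has a single radial distortion coefficient and no
  tangential terms; adequate for the simulated optics, not for severe
  wide-angle lenses.
- Wand calibration assumes two cameras; n-camera rigs would need a
  generalization of the pose initialization.
- The constant-acceleration smoother is a generic kinematic prior, not
  a flapping-flight dynamic model; within-wingbeat oscillations are
  treated as noise.
- The synthetic cohort draws flight parameters log-normally with a
  shared variance scale across parameters and realizes paths as
  helices; real tracks are less regular, so pipeline error estimates
  from synthetic data are best-case.
- Advance ratio uses a proxy for stroke amplitude; absolute values are
  comparable within this package but not across studies using
  kinematic stroke amplitude.
- The LMM layer supports a single random intercept only — exactly what
  the comparative analyses need, but not crossed or nested random
  effects.
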