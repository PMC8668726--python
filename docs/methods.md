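# Methods

This note documents the models implemented in `escapeflight`, the defaults
of the synthetic-data generator, the numerical choices made where the
design was genuinely open, and what the test suite does and does not
establish about real data.

## Study design being emulated

The unit of analysis is one upward escape flight in a 0.5 × 0.5 × 2.1 m
vertical flight tunnel, recorded by four synchronized 400 fps cameras
(1020 × 1020 px) over a 0.4 m cubic focal section centred 0.5 m above the
floor. The default cohort is 18 great tits, three per sex × treatment cell,
with treatments control (no tag), lighter tag (0.9 g) and heavier tag
(1.2 g); each bird flies five times on days 1, 7, 14 and 28 after tagging,
giving 360 flights. Analysis consumes 2D pixel tracks of the beak and both
wingtips plus manually scored downstroke-onset frames — no image
processing is performed.

## Actuator-disk model

Disk area `A = π b²max / 4` and disk loading `W/A = 4 m g / (π b²max)`,
with `g = 9.81 m/s²` exactly. Two loadings per flight: *fictive*
(bird mass) and *real* (bird + tag); their difference is exactly
`m_tag · g / A`. The tag effect on escape speed is decomposed as
`ΔU = ΔU_tag + dU/d(W/A) · ΔW_tag/A`, with both coefficients stored as
negative (speed reductions); the reporting layer prints magnitudes and
rounds percentages half away from zero to integer percent. At fixed
wingspan the conversion to a per-gram slope is
`dU/dm = dU/d(W/A) · g / A · 10⁻³` (m/s per gram). Note that with a slope
of −0.11 m² s/kg and a disk of 110 cm² this evaluates to −0.098 m/s/g; the
package computes this value rather than forcing any externally quoted
figure, since per-gram slopes quoted at rounded inputs are not generally
self-consistent.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which every downstream claim is evaluated.

Ground-truth dynamics per trial (bird *i*, treatment *tr*, day *T*):

```
speed = 5.06 − 0.11·(W_bird+tag/A) − 0.11·1[tagged] + slope_tr·T + a_i + ε
freq  = 23.0 + 0.010·T + b_i + ε_f
mass(T) = mass(1) · 1.0006^(T−1)
```

with day slopes 0.010 / 0.003 / 0.007 m/s per day for control / lighter /
heavier, bird intercepts `a_i ~ N(0, 0.10²)` m/s and `b_i ~ N(0, 0.50²)`
s⁻¹, residuals 0.25 m/s and 0.80 s⁻¹. Body masses are sex-specific
truncated normals (females N(15.0, 0.8²) g, males N(16.5, 0.8²) g, ±2 SD),
and each bird's constant wingspan is back-computed from a target fictive
loading drawn from N(18.03, 0.55²) (females) or N(17.70, 0.55²) (males)
N/m², so the cohort reproduces realistic sexed loading means and tag-mass
fractions (≈6% of body mass for the 0.9 g tag on females, ≈7–8% for the
1.2 g tag). The speed intercept 5.06 m/s places an untagged bird at
W/A = 18 N/m² at ≈3.08 m/s. The variance components are assumptions (field
studies report only standard errors of group means, which these defaults
match in magnitude); they are exposed in the config and in
`GroundTruthParams`.

Trajectories are deliberately simple plumbing: vertical ascent at the true
speed, a 5 mm vertical bob at the wingbeat frequency, a slow ~3 mm lateral
wobble, and wingtips whose span oscillates between 30% and 100% of b_max
once per wingbeat, with downstroke onsets recorded at the frames of span
maxima. Pixel noise is i.i.d. Gaussian, 0.5 px per camera/frame. Day
enters the linear predictor as its literal value T ∈ {1, 7, 14, 28}.

What the generator does **not** emulate: lens distortion, correlated or
heavy-tailed tracking errors, occlusions and digitizing lapses, wind and
wall effects, manoeuvre-to-manoeuvre changes in path shape, or any
behavioural feedback (habituation mechanisms, motivation). Passing tests
therefore show that the estimation chain is correct and well-calibrated
under the stated noise model — not that real digitized video meets that
model.

## Camera calibration and triangulation

The classical 11-parameter DLT per camera, fitted by linear least squares
from ≥6 non-coplanar bead correspondences (2n equations, 11 unknowns); no
distortion terms, no iterative refinement, no bundle adjustment.
Triangulation stacks the two linear ray equations per camera and solves by
least squares; a batched path solves the per-frame 3×3 normal equations
for whole tracks. Degeneracy rules: bead sets whose centered coordinates
have a smallest-to-largest singular-value ratio below 1e-8 are rejected as
coplanar; triangulation geometries with condition number above 1e8 are
rejected; projective denominators ≤ 0 (point behind camera) are errors.
Coordinates: right-handed tunnel frame, z up, origin at the floor centre,
metres; pixels (u, v), origin top-left, v down. The default synthetic rig
places four ideal pinhole cameras (f = 1800 px) at staggered azimuths and
heights 1.4 m from the tunnel axis; with 0.5 px noise and 30 beads,
calibration RMSE is ≈0.5 px and four-view triangulation error ≈0.2 mm.

## Track reconstruction and smoothing

Frames with <2 camera detections are linearly interpolated in 3D when the
gap is ≤3 frames; longer gaps split the track and the longest segment is
kept (flagged); segments under 10 frames make the trial unusable. Frames
are 0-indexed; frame k is at time k/fps.

Smoothing is a per-axis constant-velocity Kalman filter (state: position,
velocity; white-acceleration process noise σ_a; position measurement noise
σ_m) followed by fixed-interval RTS smoothing, so velocity estimates carry
no filter lag. The covariance recursion is shared across axes. Defaults:
σ_m = 0.7 mm (the triangulation error scale at 0.5 px pixel noise) and
σ_a = 1.0 m/s². The choice of σ_a fixes what "trajectory-average speed"
means: U is defined here as the mean Euclidean norm of the smoothed
**body-translation** velocity, so the smoother bandwidth (≈6 Hz at the
default σ_a/σ_m) is placed between the trajectory dynamics (<5 Hz for a
0.13 s near-ballistic ascent) and the ~23 Hz wingbeat. The
wingbeat-induced beak bob is thereby treated as oscillatory measurement
disturbance and suppressed; retaining it (larger σ_a) inflates U by up to
~2% and adds a phase-dependent partial-period error of ~1% per flight.
Both noise parameters are overridable per run, and a net-displacement
speed definition is available as `method="net_displacement"`. Wingbeat
frequency is `(n_onsets − 1) / (t_last − t_first)` from the scored
downstroke onsets (≥2 required); at 400 fps and ~3 wingbeats per recording
the frame-quantisation error is within ±0.5 s⁻¹. Maximum wingspan is the
largest simultaneous wingtip separation over ≥1 full wingbeat, measured
once per bird from a designated recording; sampling the span waveform at
400 fps can miss the true peak by up to ~0.6% of b_max, well under the
millimetre scale that matters for loading.

## Mixed-model inference

All models are fitted by REML with a bird-level random intercept
(statsmodels MixedLM). Main families: fictive loading ~ treatment × sex ×
day (full factorial); speed ~ loading × treatment × day, fitted with the
fictive and with the real loading; frequency ~ loading × treatment × day.
Day is numeric. Sex is excluded from the speed and frequency models because
it is collinear with disk loading. Post-hoc analyses: (a) fictive loading ~
sex + tagged + day + tagged:day; (b) speed ~ treatment for each treatment
pair, no covariates; (c) speed ~ tagged, and speed ~ tagged + day +
real loading + tagged:day.

Slopes from the factorial models are reported as **average partial
effects**: the mean of ∂ŷ/∂x over the observed design (optionally within a
treatment subset), computed exactly from design-matrix differences. Raw
main-effect coefficients in these uncentered interaction models are
evaluated at loading = 0 — an 18 N/m² extrapolation — and are therefore
nearly meaningless point estimates; the average partial effect equals the
coefficient a centered model would report and is what marginal-effects
tooling (e.g. emtrends) produces.

Numerical details: the optimiser cascade is BFGS → Powell → Nelder–Mead;
if none converges the model falls back to an OLS variance structure with
an explicit warning. A random-intercept variance on the REML boundary is
reported as 0 and flagged singular, not treated as failure (with zero
between-bird variance the fixed effects then equal OLS exactly). Wald
tests use large-sample normal statistics; exact small-sample denominator
degrees of freedom are deliberately out of scope, since they differ across
implementations and the recovery targets are coefficients, not F values.
"Percent change over the study" spans day 1 → day 28 (27 days) and is
reported at 0.1% precision, which is robust to the 27-vs-28-day ambiguity
in how such spans are quoted.

## Pipeline, seeding and problem sizes

The staged pipeline writes plain CSV/JSON only, one directory per run,
with a manifest carrying the config hash and seed. Per-stage RNGs are
children of `SeedSequence(master_seed)` spawned in the fixed order cohort,
trials, scenes, calibration; identical seeds give byte-identical outputs.
The in-memory replicate loop (`recovery_study`) runs the same computation
without file I/O; `mode="video"` is the full videogrammetry chain,
`mode="truth"` isolates the statistical stage. Replicate studies use 200
replicates of the default 360-flight design in the acceptance script
(video mode) and in the recovery acceptance test (truth mode); these sizes
put the Monte-Carlo error of the mean estimates an order of magnitude
below the recovery tolerances.

## Known limitations

- The linear DLT without distortion cannot represent real lenses; real
  calibrations need distortion handling or pre-undistorted tracks.
- The constant-velocity smoother is matched to short near-ballistic
  ascents; strongly curved escape paths would argue for a
  constant-acceleration state or a larger σ_a, changing what U measures.
- The tag-effect decomposition is a local linear model around the observed
  loading range (~16–20 N/m²); extrapolating to very heavy tags or other
  body plans is unsupported.
- Mixed-model p-values use normal approximations; small-sample inference
  (Satterthwaite/Kenward–Roger) is not implemented.
- The generator's variance components are assumptions chosen to match the
  magnitude of reported group-mean standard errors; absolute power
  calculations inherit that assumption.
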