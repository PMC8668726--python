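"""Synthetic escape-flight study generator.

Emulates the full experiment that the analysis pipeline consumes: an 18-bird
great-tit cohort (3 birds per sex x treatment cell; treatments control /
0.9 g lighter tag / 1.2 g heavier tag), escape-flight trials on days 1, 7, 14
and 28 after tagging with five flights per bird per day, ground-truth flight
speed and wingbeat-frequency dynamics, a four-camera 400 fps rig around a
vertical flight tunnel, projected 2D pixel tracks of beak and wingtips, and
calibration-bead fields.

Ground-truth dynamics (per trial)::

    speed = speed_intercept + speed_loading_slope * W_total/A
            + tag_offset * 1[tagged] + day_slope(treatment) * T
            + bird_intercept + N(0, residual_sd_speed)
    freq  = freq_baseline + freq_day_slope * T
            + bird_intercept + N(0, residual_sd_freq)
    mass(T) = mass(day 1) * (1 + mass_drift_frac_per_day)^(T - 1)

so that with the default coefficients the cohort reproduces the field
estimates the model is meant to recover: a speed-vs-disk-loading slope of
-0.11 m^2 s/kg, a -0.11 m/s mass-independent tag offset, per-treatment daily
speed slopes of 0.010 / 0.003 / 0.007 m/s per day, a wingbeat-frequency
trend of 0.010 s^-1 per day around a 23 s^-1 baseline, and a 0.06%/day body
mass gain.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .aerodisk import G, disk_loading
from .calib import DLTCoefficients, project

SEXES = ("female", "male")
TREATMENTS = ("control", "lighter_tag", "heavier_tag")
TAG_MASS_G = {"control": 0.0, "lighter_tag": 0.9, "heavier_tag": 1.2}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GroundTruthParams:
    """All tunable generator parameters with the default study conditions."""

    # speed model, m/s
    speed_intercept: float = 5.06
    speed_loading_slope: float = -0.11     # m^2 s/kg
    tag_offset: float = -0.11              # m/s, mass-independent tag effect
    speed_day_slope_by_treatment: dict = field(default_factory=lambda: {
        "control": 0.010, "lighter_tag": 0.003, "heavier_tag": 0.007})
    # wingbeat frequency model, s^-1
    freq_baseline: float = 23.0
    freq_day_slope: float = 0.010
    # body-mass dynamics
    mass_drift_frac_per_day: float = 0.0006
    # morphometrics
    body_mass_mean_g: dict = field(default_factory=lambda: {
        "female": 15.0, "male": 16.5})
    body_mass_sd_g: float = 0.8            # truncated at +/- 2 SD
    target_loading_mean: dict = field(default_factory=lambda: {
        "female": 18.03, "male": 17.70})   # N/m^2, sets b_max from mass
    target_loading_sd: float = 0.55
    # variance components
    bird_intercept_sd_speed: float = 0.10
    bird_intercept_sd_freq: float = 0.50
    residual_sd_speed: float = 0.25
    residual_sd_freq: float = 0.80
    # observation model
    pixel_noise_sd: float = 0.5            # px
    bob_amplitude_m: float = 0.005         # vertical beak bob per wingbeat
    lateral_wobble_sd_m: float = 0.003
    # design
    birds_per_cell: int = 3
    test_days: tuple = (1, 7, 14, 28)
    flights_per_day: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("body_mass_sd_g", "target_loading_sd",
                     "bird_intercept_sd_speed", "bird_intercept_sd_freq",
                     "residual_sd_speed", "residual_sd_freq",
                     "pixel_noise_sd", "bob_amplitude_m", "lateral_wobble_sd_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.birds_per_cell < 1:
            raise ConfigurationError("birds_per_cell must be >= 1")
        if self.flights_per_day < 1:
            raise ConfigurationError("flights_per_day must be >= 1")
        scalars = [self.speed_intercept, self.speed_loading_slope,
                   self.tag_offset, self.freq_baseline, self.freq_day_slope,
                   self.mass_drift_frac_per_day]
        scalars += list(self.speed_day_slope_by_treatment.values())
        if not all(math.isfinite(v) for v in scalars):
            raise ConfigurationError("model coefficients must be finite")
        if set(self.speed_day_slope_by_treatment) != set(TREATMENTS):
            raise ConfigurationError(
                f"day slopes must be given for treatments {TREATMENTS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["test_days"] = list(self.test_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthParams":
        d = dict(d)
        if "test_days" in d:
            d["test_days"] = tuple(d["test_days"])
        p = cls(**d)
        p.validate()
        return p


@dataclass(frozen=True)
class BirdSpec:
    bird_id: str
    sex: str
    treatment: str
    tag_mass_g: float
    body_mass_day1_g: float
    wingspan_bmax_m: float
    random_intercept_speed: float
    random_intercept_freq: float

    @property
    def tagged(self) -> bool:
        return self.tag_mass_g > 0


@dataclass(frozen=True)
class TrialPlan:
    trial_id: str
    bird_id: str
    test_day: int
    flight_index: int
    body_mass_on_day_g: float
    loading_real: float      # (bird+tag) disk loading used by the speed model
    true_speed: float        # m/s
    true_freq: float         # s^-1


@dataclass(frozen=True)
class CameraRig:
    cameras: list            # list of DLTCoefficients (ground-truth cameras)
    fps: float = 400.0
    resolution: tuple = (1020, 1020)
    focal_center: tuple = (0.0, 0.0, 0.5)
    focal_size: float = 0.4  # metres, cubic recording section

    @property
    def focal_lo(self):
        c = np.asarray(self.focal_center)
        return c - self.focal_size / 2.0

    @property
    def focal_hi(self):
        c = np.asarray(self.focal_center)
        return c + self.focal_size / 2.0


@dataclass(frozen=True)
class CalibrationField:
    positions: np.ndarray    # (n, 3) bead positions, metres
    pixels: dict             # camera index -> (n, 2) pixel observations


@dataclass(frozen=True)
class SceneRecording:
    trial: TrialPlan
    times: np.ndarray                   # (n,) seconds, frame k at k/fps
    pixel_tracks: dict                  # point -> (n_cameras, n, 2) pixels
    downstroke_onset_frames: np.ndarray
    truth_positions: dict               # point -> (n, 3) ground-truth metres
    bmax_true: float


# ---------------------------------------------------------------------------
# camera rig


def _camera_dlt(position, target, f_px, cx, cy) -> DLTCoefficients:
    """Exact DLT coefficients of an ideal pinhole camera at ``position``
    looking at ``target`` (world z up; pixel v runs downward)."""
    position = np.asarray(position, dtype=float)
    z_cam = np.asarray(target, dtype=float) - position
    z_cam /= np.linalg.norm(z_cam)
    up = np.array([0.0, 0.0, 1.0])
    x_cam = np.cross(z_cam, up)
    if np.linalg.norm(x_cam) < 1e-9:
        raise ConfigurationError("camera optical axis parallel to vertical")
    x_cam /= np.linalg.norm(x_cam)
    y_cam = np.cross(z_cam, x_cam)  # points downward in the image
    R = np.stack([x_cam, y_cam, z_cam])
    t = -R @ position
    K = np.array([[f_px, 0.0, cx], [0.0, f_px, cy], [0.0, 0.0, 1.0]])
    P = K @ np.column_stack([R, t])
    if abs(P[2, 3]) < 1e-12:
        raise ConfigurationError("degenerate camera placement (origin on image plane)")
    P = P / P[2, 3]
    L = np.concatenate([P[0], P[1], P[2, :3]])
    return DLTCoefficients(L=L)


def default_rig(fps: float = 400.0) -> CameraRig:
    """Four synchronised cameras around the tunnel, staggered in azimuth and
    height so the geometry is non-degenerate, all covering the 0.4 m cubic
    recording section centred 0.5 m above the tunnel floor."""
    target = np.array([0.0, 0.0, 0.5])
    cams = []
    radius = 1.4
    heights = [0.35, 0.62, 0.42, 0.58]
    for i, (az_deg, h) in enumerate(zip((0, 90, 180, 270), heights)):
        az = math.radians(az_deg + 7 * i)  # slight stagger breaks symmetry
        pos = [radius * math.cos(az), radius * math.sin(az), h]
        cams.append(_camera_dlt(pos, target, f_px=1800.0, cx=510.0, cy=510.0))
    return CameraRig(cameras=cams, fps=fps)


# ---------------------------------------------------------------------------
# cohort and trials


def _truncnorm(rng, mean, sd, nsd=2.0):
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= nsd * sd:
            return x


def generate_cohort(params: GroundTruthParams, rng=None) -> list[BirdSpec]:
    """Draw the balanced cohort: ``birds_per_cell`` birds per sex x treatment.

    Body masses come from sex-specific truncated normals; each bird's
    (constant) maximum wingspan is back-computed from a drawn target disk
    loading, so the cohort reproduces realistic sexed loading means and
    tag-mass fractions (~5-6% of body mass for the 0.9 g tag, ~7-8% for the
    1.2 g tag).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    birds = []
    i = 0
    for sex in SEXES:
        for tr in TREATMENTS:
            for _ in range(params.birds_per_cell):
                mass = _truncnorm(rng, params.body_mass_mean_g[sex],
                                  params.body_mass_sd_g)
                loading = _truncnorm(rng, params.target_loading_mean[sex],
                                     params.target_loading_sd)
                bmax = math.sqrt(4.0 * mass * 1e-3 * G / (math.pi * loading))
                birds.append(BirdSpec(
                    bird_id=f"bird{i:02d}",
                    sex=sex,
                    treatment=tr,
                    tag_mass_g=TAG_MASS_G[tr],
                    body_mass_day1_g=mass,
                    wingspan_bmax_m=bmax,
                    random_intercept_speed=rng.normal(0, params.bird_intercept_sd_speed),
                    random_intercept_freq=rng.normal(0, params.bird_intercept_sd_freq),
                ))
                i += 1
    return birds


def simulate_trials(cohort: list[BirdSpec], params: GroundTruthParams,
                    rng=None) -> list[TrialPlan]:
    """Roll the cohort through the trial schedule and draw ground truth.

    Five flights per bird per test day by default; each trial's true speed
    and wingbeat frequency follow the linear mixed structure documented in
    the module docstring, with the bird's (bird+tag)/A disk loading computed
    from its drifted body mass on that day.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    trials = []
    for bird in cohort:
        day_slope = params.speed_day_slope_by_treatment[bird.treatment]
        for day in params.test_days:
            mass_day = bird.body_mass_day1_g * (
                (1.0 + params.mass_drift_frac_per_day) ** (day - 1))
            loading = disk_loading((mass_day + bird.tag_mass_g) * 1e-3,
                                   bird.wingspan_bmax_m)
            mu_speed = (params.speed_intercept
                        + params.speed_loading_slope * loading
                        + params.tag_offset * (1.0 if bird.tagged else 0.0)
                        + day_slope * day
                        + bird.random_intercept_speed)
            mu_freq = (params.freq_baseline
                       + params.freq_day_slope * day
                       + bird.random_intercept_freq)
            for k in range(1, params.flights_per_day + 1):
                speed = mu_speed + rng.normal(0, params.residual_sd_speed)
                freq = mu_freq + rng.normal(0, params.residual_sd_freq)
                if speed <= 0.5:  # escape flights are fast; re-draw outliers
                    speed = max(mu_speed, 0.5)
                trials.append(TrialPlan(
                    trial_id=f"{bird.bird_id}_d{day:02d}_f{k}",
                    bird_id=bird.bird_id,
                    test_day=day,
                    flight_index=k,
                    body_mass_on_day_g=mass_day,
                    loading_real=loading,
                    true_speed=speed,
                    true_freq=freq,
                ))
    return trials


# ---------------------------------------------------------------------------
# trajectories and recordings


def synthesize_trajectory(trial: TrialPlan, rig: CameraRig, bird: BirdSpec,
                          params: GroundTruthParams, rng=None) -> SceneRecording:
    """Render one escape flight into per-camera pixel tracks.

    The beak ascends vertically at the trial's true speed through the 0.4 m
    recording section, with a small vertical bob at the wingbeat frequency
    and a slow lateral wobble.  Wingtips sit symmetrically about the body
    axis with an instantaneous span that peaks at the bird's b_max once per
    wingbeat; downstroke onsets are recorded at the frames of span maxima.
    All three points are projected through every camera with i.i.d. Gaussian
    pixel noise.
    """
    if trial.true_speed <= 0 or trial.true_freq <= 0:
        raise ConfigurationError("true speed and wingbeat frequency must be positive")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 2)
    fps = rig.fps
    lo, hi = rig.focal_lo, rig.focal_hi
    U, f = trial.true_speed, trial.true_freq
    duration = (hi[2] - lo[2]) / U
    n = max(int(math.floor(duration * fps)) + 1, 3)
    t = np.arange(n) / fps

    phase_bob = rng.uniform(0, 2 * math.pi)
    phase_span = rng.uniform(0, 2 * math.pi)
    x0 = rng.uniform(-0.03, 0.03)
    y0 = rng.uniform(-0.03, 0.03)

    # slow lateral wobble: two incommensurate low-frequency sinusoids whose
    # combined sd is lateral_wobble_sd_m
    amp = params.lateral_wobble_sd_m
    wx = amp * (np.sin(2 * np.pi * 2.3 * t + rng.uniform(0, 2 * np.pi))
                + 0.5 * np.sin(2 * np.pi * 4.1 * t + rng.uniform(0, 2 * np.pi)))
    wy = amp * (np.sin(2 * np.pi * 1.9 * t + rng.uniform(0, 2 * np.pi))
                + 0.5 * np.sin(2 * np.pi * 3.7 * t + rng.uniform(0, 2 * np.pi)))

    beak = np.column_stack([
        x0 + wx,
        y0 + wy,
        lo[2] + U * t + params.bob_amplitude_m * np.sin(2 * np.pi * f * t + phase_bob),
    ])

    # instantaneous wingspan: peaks at b_max at downstroke onset
    span = bird.wingspan_bmax_m * (0.65 + 0.35 * np.cos(2 * np.pi * f * t - phase_span))
    body = beak + np.array([0.0, 0.0, -0.02])  # shoulder line a bit below beak
    flap_z = 0.25 * span * np.sin(2 * np.pi * f * t - phase_span)  # stroke arc
    ltip = body + np.column_stack([-span / 2, np.zeros(n), flap_z])
    rtip = body + np.column_stack([span / 2, np.zeros(n), flap_z])

    # downstroke onsets: frames nearest the span maxima (phase = 2 pi k)
    onsets = []
    kk = 0
    while True:
        tk = (kk + phase_span / (2 * math.pi)) / f
        if tk > t[-1] + 1e-12:
            break
        frame = int(round(tk * fps))
        if 0 <= frame < n:
            onsets.append(frame)
        kk += 1
    onset_frames = np.unique(np.asarray(onsets, dtype=int))

    truth = {"beak": beak, "ltip": ltip, "rtip": rtip}
    pixel_tracks = {}
    res = rig.resolution
    for name, pts in truth.items():
        cams = np.empty((len(rig.cameras), n, 2))
        for ci, cam in enumerate(rig.cameras):
            px = project(cam, pts)
            if params.pixel_noise_sd > 0:
                px = px + rng.normal(0, params.pixel_noise_sd, size=px.shape)
            cams[ci] = px
        pixel_tracks[name] = np.clip(cams, [0.0, 0.0],
                                     [res[0] - 1.0, res[1] - 1.0])
    return SceneRecording(
        trial=trial, times=t, pixel_tracks=pixel_tracks,
        downstroke_onset_frames=onset_frames, truth_positions=truth,
        bmax_true=bird.wingspan_bmax_m)


def generate_calibration_field(rig: CameraRig, n_beads: int = 30,
                               seed: int | None = 0,
                               pixel_noise_sd: float = 0.0) -> CalibrationField:
    """Scatter calibration beads uniformly through the recording section and
    project them through every camera (exact pixels unless noise requested).

    Bead sets that come out nearly coplanar are rejected and redrawn.
    """
    if n_beads < 6:
        raise ConfigurationError(
            f"DLT calibration needs >= 6 beads, got {n_beads} (11 unknowns)")
    rng = np.random.default_rng(seed)
    lo, hi = rig.focal_lo, rig.focal_hi
    for _ in range(100):
        pts = rng.uniform(lo, hi, size=(n_beads, 3))
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] / sv[0] > 1e-3:  # comfortably non-coplanar
            break
    else:  # pragma: no cover - uniform draws are essentially never coplanar
        raise ConfigurationError("could not draw a non-coplanar bead field")
    pixels = {}
    for ci, cam in enumerate(rig.cameras):
        px = project(cam, pts)
        if pixel_noise_sd > 0:
            px = px + rng.normal(0, pixel_noise_sd, size=px.shape)
        pixels[ci] = px
    return CalibrationField(positions=pts, pixels=pixels)
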