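"""End-to-end orchestration: simulate -> calibrate -> kinematics ->
aggregate -> infer, plus the replicate parameter-recovery loop.

Two execution styles:

* :func:`run_pipeline` — the staged, file-based run (plain CSV/JSON in one
  run directory, each stage re-runnable from the previous stage's outputs,
  manifest with seed and config hash).
* :func:`run_study` / :func:`recovery_study` — the same computation kept in
  memory, used for replicate simulation studies where writing 1400 track
  files per replicate would dominate the cost.

Seeding: every stage draws from a child of ``numpy.random.SeedSequence(seed)``
spawned in a fixed documented order (cohort, trials, scenes, calibration), so
a master seed reproduces the whole run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aerodisk, calib, inference, kinematics, synthgen
from .synthgen import CameraRig, GroundTruthParams

log = logging.getLogger("escapeflight")

STAGES = ("simulate", "calibrate", "kinematics", "aggregate", "infer")


class PipelineError(RuntimeError):
    """A stage is missing its upstream outputs or its config is invalid."""


@dataclass
class RunConfig:
    params: GroundTruthParams = field(default_factory=GroundTruthParams)
    seed: int = 0
    stages: tuple = STAGES
    n_beads: int = 30
    bead_pixel_noise_sd: float | None = None   # default: params.pixel_noise_sd
    kalman_process_noise: float = 1.0           # m/s^2 acceleration SD
    kalman_measurement_noise: float = 7e-4     # m position SD
    speed_method: str = "mean_norm"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = GroundTruthParams.from_dict(raw.pop("params", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        try:
            return cls(params=params, **raw)
        except TypeError as exc:
            raise PipelineError(f"invalid config key: {exc}") from exc

    def to_dict(self) -> dict:
        d = {"params": self.params.to_dict(), "seed": self.seed,
             "stages": list(self.stages), "n_beads": self.n_beads,
             "bead_pixel_noise_sd": self.bead_pixel_noise_sd,
             "kalman_process_noise": self.kalman_process_noise,
             "kalman_measurement_noise": self.kalman_measurement_noise,
             "speed_method": self.speed_method}
        return d


def _stage_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("cohort", "trials", "scenes", "calibration")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def cohort_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame([{
        "bird_id": b.bird_id, "sex": b.sex, "treatment": b.treatment,
        "tag_mass_g": b.tag_mass_g, "body_mass_g": b.body_mass_day1_g,
        "bmax_m": b.wingspan_bmax_m} for b in cohort])


def trials_frame(trials) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": t.trial_id, "bird_id": t.bird_id, "test_day": t.test_day,
        "flight_index": t.flight_index, "body_mass_g": t.body_mass_on_day_g}
        for t in trials])


# ---------------------------------------------------------------------------
# in-memory study


def run_study(params: GroundTruthParams, seed: int = 0, *,
              rig: CameraRig | None = None, mode: str = "video",
              n_beads: int = 30, kalman_process_noise: float = 1.0,
              kalman_measurement_noise: float = 7e-4) -> dict:
    """Generate one synthetic study and measure it end to end.

    ``mode="video"`` runs the full chain: project trajectories to pixels,
    calibrate cameras from a bead field, triangulate, smooth and reduce.
    ``mode="truth"`` short-circuits the videogrammetry and analyses the
    generator's true per-trial speed/frequency/morphometrics — the
    statistical stage under perfect measurement.

    Returns a dict with the cohort, trials, measured flight results and the
    assembled analysis table.
    """
    if mode not in ("video", "truth"):
        raise PipelineError(f"unknown study mode {mode!r}")
    rngs = _stage_rngs(seed)
    cohort = synthgen.generate_cohort(params, rng=rngs["cohort"])
    trials = synthgen.simulate_trials(cohort, params, rng=rngs["trials"])
    cdf = cohort_frame(cohort)
    birds = {b.bird_id: b for b in cohort}

    if mode == "truth":
        flights = pd.DataFrame([{
            "trial_id": t.trial_id, "bird_id": t.bird_id,
            "test_day": t.test_day, "flight_index": t.flight_index,
            "body_mass_g": t.body_mass_on_day_g, "mean_speed": t.true_speed,
            "wingbeat_freq": t.true_freq, "n_downstrokes": -1, "qc": ""}
            for t in trials])
        bmax = cdf[["bird_id", "bmax_m"]].copy()
    else:
        rig = rig or synthgen.default_rig()
        noise = params.pixel_noise_sd
        beads = synthgen.generate_calibration_field(
            rig, n_beads=n_beads, seed=rngs["calibration"],
            pixel_noise_sd=noise)
        dlts = [calib.fit_dlt(beads.positions, beads.pixels[ci],
                              camera_id=f"cam{ci}")
                for ci in range(len(rig.cameras))]
        rows, bmax_rows = [], {}
        for t in trials:
            rec = synthgen.synthesize_trajectory(
                t, rig, birds[t.bird_id], params, rng=rngs["scenes"])
            r = kinematics.analyze_recording(
                rec, dlts, process_noise=kalman_process_noise,
                measurement_noise=kalman_measurement_noise, fps=rig.fps)
            rows.append({
                "trial_id": r.trial_id, "bird_id": r.bird_id,
                "test_day": r.test_day, "flight_index": r.flight_index,
                "body_mass_g": r.body_mass_g, "mean_speed": r.mean_speed,
                "wingbeat_freq": r.wingbeat_freq,
                "n_downstrokes": r.n_downstrokes,
                "qc": ";".join(r.qc_flags)})
            if t.bird_id not in bmax_rows:  # one designated recording per bird
                onsets = rec.downstroke_onset_frames / rig.fps
                left = kinematics.reconstruct_track(
                    rec.pixel_tracks["ltip"], dlts, rig.fps)
                right = kinematics.reconstruct_track(
                    rec.pixel_tracks["rtip"], dlts, rig.fps)
                bmax_rows[t.bird_id] = kinematics.max_wingspan(
                    left, right, onsets if len(onsets) >= 2 else None)
        flights = pd.DataFrame(rows)
        bmax = pd.DataFrame({"bird_id": list(bmax_rows),
                             "bmax_m": list(bmax_rows.values())})

    measured_cohort = cdf.drop(columns="bmax_m").merge(bmax, on="bird_id")
    records = aerodisk.build_loading_records(measured_cohort, flights)
    table = inference.build_analysis_table(cdf, records)
    return {"cohort": cohort, "cohort_frame": cdf, "trials": trials,
            "flights": flights, "bmax": bmax, "loading_records": records,
            "table": table}


def recovery_study(params: GroundTruthParams, n_replicates: int, seed: int = 0,
                   *, mode: str = "video", **study_kwargs) -> pd.DataFrame:
    """Replicate the full study ``n_replicates`` times and collect the
    mixed-model estimates that parameter recovery is judged on.

    Per replicate: fit M2 (speed ~ real loading x treatment x day) and M3
    (frequency ~ real loading x treatment x day), extract the marginal
    loading slope, per-treatment day slopes, and the frequency day slope.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for i, child in enumerate(children):
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        study = run_study(params, seed=rep_seed, mode=mode, **study_kwargs)
        table = study["table"]
        fits = {
            "speed_real": inference._fit_mixedlm(
                "U ~ loading_real * treatment * day", table, "speed_real"),
            "freq": inference._fit_mixedlm(
                "f ~ loading_real * treatment * day", table, "freq"),
        }
        day_slopes = inference.day_slope_by_treatment(fits["speed_real"], table)
        tagged = (table["treatment"] != "control").to_numpy()
        rows.append({
            "replicate": i, "seed": rep_seed,
            "loading_slope": inference.average_partial_effect(
                fits["speed_real"], table, "loading_real"),
            "day_slope_control": day_slopes["control"],
            "day_slope_lighter": day_slopes["lighter_tag"],
            "day_slope_heavier": day_slopes["heavier_tag"],
            "day_slope_untagged": inference.average_partial_effect(
                fits["speed_real"], table, "day", subset=~tagged),
            "day_slope_tagged": inference.average_partial_effect(
                fits["speed_real"], table, "day", subset=tagged),
            "freq_day_slope": inference.average_partial_effect(
                fits["freq"], table, "day"),
            "converged": fits["speed_real"].converged and fits["freq"].converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staged, file-based pipeline


def _require(outdir: Path, *names):
    for name in names:
        if not (outdir / name).exists():
            raise PipelineError(
                f"stage input {name!r} missing from {outdir}; "
                "run the upstream stage first")


def stage_simulate(config: RunConfig, outdir: Path, rig: CameraRig) -> None:
    params = config.params
    rngs = _stage_rngs(config.seed)
    cohort = synthgen.generate_cohort(params, rng=rngs["cohort"])
    trials = synthgen.simulate_trials(cohort, params, rng=rngs["trials"])
    birds = {b.bird_id: b for b in cohort}

    cohort_frame(cohort).to_csv(outdir / "cohort.csv", index=False)
    trials_frame(trials).to_csv(outdir / "trials.csv", index=False)

    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "downstrokes").mkdir(exist_ok=True)
    truth = {}
    for t in trials:
        rec = synthgen.synthesize_trajectory(t, rig, birds[t.bird_id], params,
                                             rng=rngs["scenes"])
        n = len(rec.times)
        for ci in range(len(rig.cameras)):
            parts = []
            for point, tracks in rec.pixel_tracks.items():
                parts.append(pd.DataFrame({
                    "frame": np.arange(n), "point": point,
                    "u_px": tracks[ci, :, 0], "v_px": tracks[ci, :, 1]}))
            pd.concat(parts).to_csv(
                outdir / "tracks" / f"{t.trial_id}_cam{ci}.csv", index=False)
        pd.DataFrame({"frame": rec.downstroke_onset_frames}).to_csv(
            outdir / "downstrokes" / f"{t.trial_id}.csv", index=False)
        truth[t.trial_id] = {"true_speed": t.true_speed,
                             "true_freq": t.true_freq,
                             "loading_real": t.loading_real}
    (outdir / "calibration").mkdir(exist_ok=True)
    noise = (config.bead_pixel_noise_sd if config.bead_pixel_noise_sd is not None
             else params.pixel_noise_sd)
    beads = synthgen.generate_calibration_field(
        rig, n_beads=config.n_beads, seed=rngs["calibration"],
        pixel_noise_sd=noise)
    rows = []
    for ci, px in beads.pixels.items():
        for bi in range(len(beads.positions)):
            x, y, z = beads.positions[bi]
            rows.append({"bead_id": bi, "x": x, "y": y, "z": z,
                         "camera": f"cam{ci}", "u_px": px[bi, 0],
                         "v_px": px[bi, 1]})
    pd.DataFrame(rows).to_csv(outdir / "calibration" / "beads.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({"params": params.to_dict(), "trials": truth}, fh, indent=1)
    log.info("simulate: %d birds, %d trials", len(cohort), len(trials))


def stage_calibrate(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "calibration/beads.csv")
    beads = pd.read_csv(outdir / "calibration" / "beads.csv")
    rows = []
    for cam, sub in beads.groupby("camera"):
        dlt = calib.fit_dlt(sub[["x", "y", "z"]].to_numpy(),
                            sub[["u_px", "v_px"]].to_numpy(), camera_id=cam)
        row = {"camera_id": cam, "rmse_px": dlt.reprojection_rmse,
               "n_points": dlt.n_points_used}
        row.update({f"L{i + 1}": v for i, v in enumerate(dlt.L)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "calibration" / "dlt_coefficients.csv",
                              index=False)
    log.info("calibrate: %d cameras", len(rows))


def _load_dlts(outdir: Path):
    df = pd.read_csv(outdir / "calibration" / "dlt_coefficients.csv")
    df = df.sort_values("camera_id")
    dlts = []
    for _, row in df.iterrows():
        L = np.array([row[f"L{i + 1}"] for i in range(11)])
        dlts.append(calib.DLTCoefficients(
            L=L, reprojection_rmse=row["rmse_px"],
            n_points_used=int(row["n_points"]), camera_id=row["camera_id"]))
    return dlts


def stage_kinematics(config: RunConfig, outdir: Path, rig: CameraRig) -> None:
    _require(outdir, "trials.csv", "calibration/dlt_coefficients.csv", "tracks")
    dlts = _load_dlts(outdir)
    trials = pd.read_csv(outdir / "trials.csv")
    fps = rig.fps
    rows, bmax_rows = [], {}
    for _, t in trials.iterrows():
        tracks = {}
        for ci in range(len(dlts)):
            df = pd.read_csv(outdir / "tracks" / f"{t.trial_id}_cam{ci}.csv")
            for point, sub in df.groupby("point"):
                tracks.setdefault(point, []).append(
                    sub.sort_values("frame")[["u_px", "v_px"]].to_numpy())
        tracks = {p: np.stack(v) for p, v in tracks.items()}
        onsets_df = pd.read_csv(outdir / "downstrokes" / f"{t.trial_id}.csv")
        onsets = onsets_df["frame"].to_numpy() / fps
        qc = []
        try:
            track = kinematics.reconstruct_track(tracks["beak"], dlts, fps)
            smoothed = kinematics.kalman_smooth(
                track, config.kalman_process_noise,
                config.kalman_measurement_noise)
            speed = kinematics.trajectory_average_speed(
                smoothed, method=config.speed_method)
            qc.extend(track.qc_flags)
        except (kinematics.TrackError, calib.CalibrationError) as exc:
            speed = float("nan")
            qc.append(f"unusable:{exc}")
        freq = (kinematics.wingbeat_frequency(onsets) if len(onsets) >= 2
                else float("nan"))
        rows.append({"trial_id": t.trial_id, "bird_id": t.bird_id,
                     "test_day": t.test_day, "flight_index": t.flight_index,
                     "body_mass_g": t.body_mass_g, "mean_speed": speed,
                     "wingbeat_freq": freq, "n_downstrokes": len(onsets),
                     "qc": ";".join(qc)})
        if t.bird_id not in bmax_rows:
            left = kinematics.reconstruct_track(tracks["ltip"], dlts, fps)
            right = kinematics.reconstruct_track(tracks["rtip"], dlts, fps)
            bmax_rows[t.bird_id] = kinematics.max_wingspan(
                left, right, onsets if len(onsets) >= 2 else None)
    pd.DataFrame(rows).to_csv(outdir / "flight_results.csv", index=False)
    pd.DataFrame({"bird_id": list(bmax_rows),
                  "bmax_m": list(bmax_rows.values())}).to_csv(
        outdir / "bmax_measured.csv", index=False)
    log.info("kinematics: %d flights, %d birds with wingspan", len(rows),
             len(bmax_rows))


def stage_aggregate(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "cohort.csv", "flight_results.csv", "bmax_measured.csv")
    cohort = pd.read_csv(outdir / "cohort.csv")
    flights = pd.read_csv(outdir / "flight_results.csv")
    bmax = pd.read_csv(outdir / "bmax_measured.csv")
    measured = cohort.drop(columns="bmax_m").merge(bmax, on="bird_id")
    records = aerodisk.build_loading_records(measured, flights)
    records.to_csv(outdir / "disk_loading.csv", index=False)
    log.info("aggregate: %d loading records", len(records))


def stage_infer(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "cohort.csv", "disk_loading.csv")
    cohort = pd.read_csv(outdir / "cohort.csv")
    records = pd.read_csv(outdir / "disk_loading.csv")
    table = inference.build_analysis_table(cohort, records)
    fits = inference.fit_main_models(table)
    posthoc = inference.posthoc_contrasts(table)
    summary = inference.summarize_group_effects(table, fits)

    with open(outdir / "model_fits.json", "w") as fh:
        json.dump({k: f.to_jsonable() for k, f in {**fits, **posthoc}.items()},
                  fh, indent=1)
    contrast_rows = []
    for name, f in posthoc.items():
        for term, est in f.fe_params.items():
            contrast_rows.append({"model": name, "term": term, "estimate": est,
                                  "se": f.fe_se[term]})
    pd.DataFrame(contrast_rows).to_csv(outdir / "contrasts.csv", index=False)

    day_slopes = inference.day_slope_by_treatment(fits["speed_real"], table)
    lines = [
        "# Escape-flight analysis summary", "",
        f"- flights analysed: {len(table)} from {table.bird_id.nunique()} birds",
        f"- marginal speed-vs-loading slope (real loading): "
        f"{inference.average_partial_effect(fits['speed_real'], table, 'loading_real'):.4f} m^2 s/kg",
        f"- per-treatment day slopes (m/s per day): "
        + ", ".join(f"{k}: {v:.4f}" for k, v in day_slopes.items()),
        f"- wingbeat-frequency day slope: "
        f"{inference.average_partial_effect(fits['freq'], table, 'day'):.4f} s^-1 per day",
        f"- untagged U: {summary['groups']['untagged']['U_mean']:.3f} m/s, "
        f"tagged U: {summary['groups']['tagged']['U_mean']:.3f} m/s "
        f"({summary['percent_speed_reduction_tagged']}% reduction)",
    ]
    if "percent_freq_change_over_study" in summary:
        lines.append(f"- wingbeat-frequency change over the study: "
                     f"{summary['percent_freq_change_over_study']}%")
    (outdir / "summary_report.md").write_text("\n".join(lines) + "\n")
    log.info("infer: %d models fitted", len(fits) + len(posthoc))


def run_pipeline(config: RunConfig, outdir, rig: CameraRig | None = None) -> Path:
    """Execute the enabled stages in order into ``outdir``; returns the run
    directory.  A manifest records the config, its hash and the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rig = rig or synthgen.default_rig()
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        if stage == "simulate":
            stage_simulate(config, outdir, rig)
        elif stage == "calibrate":
            stage_calibrate(config, outdir)
        elif stage == "kinematics":
            stage_kinematics(config, outdir, rig)
        elif stage == "aggregate":
            stage_aggregate(config, outdir)
        elif stage == "infer":
            stage_infer(config, outdir)
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": cfg, "config_sha256": digest,
                   "seed": config.seed, "stages_run": list(config.stages)},
                  fh, indent=1)
    return outdir
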