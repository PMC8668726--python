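"""Per-flight kinematics: 3D track reconstruction, Kalman/RTS smoothing,
trajectory-average speed, wingbeat frequency and maximum wingspan.

The measurement chain mirrors standard high-speed videogrammetry practice:
stereo tracks of the beak are triangulated frame by frame into a 3D path
X(t), smoothed with a constant-velocity Kalman filter plus fixed-interval
(Rauch-Tung-Striebel) smoothing to get the velocity series U(t), and
summarised as the trajectory-average speed U = mean ||U(t)||.  Wingbeat
frequency comes from the manually scored downstroke-onset frames, and the
maximum wingspan b_max from the largest simultaneous wingtip separation over
at least one full wingbeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calib import triangulate_tracks


class TrackError(ValueError):
    """A track cannot be reconstructed or analysed (too short, missing
    views, invalid smoother parameters...)."""


@dataclass(frozen=True)
class Track3D:
    times: np.ndarray        # (n,) seconds, uniform spacing 1/fps
    positions: np.ndarray    # (n, 3) metres
    residuals: np.ndarray    # (n,) mean per-camera reprojection residual, px
    fps: float
    qc_flags: tuple = ()

    def __post_init__(self):
        if len(self.times) != len(self.positions):
            raise TrackError("times and positions length mismatch")


@dataclass(frozen=True)
class SmoothedTrack:
    times: np.ndarray
    positions: np.ndarray    # (n, 3) smoothed metres
    velocities: np.ndarray   # (n, 3) m/s
    process_noise: float
    measurement_noise: float


@dataclass(frozen=True)
class FlightTrialResult:
    trial_id: str
    bird_id: str
    test_day: int
    flight_index: int
    mean_speed: float        # U, m/s
    wingbeat_freq: float     # f, s^-1
    n_downstrokes: int
    body_mass_g: float = float("nan")
    qc_flags: tuple = ()


# ---------------------------------------------------------------------------
# reconstruction


def _fill_gaps(points: np.ndarray, max_gap: int = 3):
    """Linearly interpolate interior NaN runs of length <= max_gap; return
    (filled points, list of valid segments as (start, stop) slices)."""
    n = len(points)
    bad = np.isnan(points).any(axis=1)
    filled = points.copy()
    # identify NaN runs
    runs = []
    i = 0
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    breaks = []
    for i, j in runs:
        interior = i > 0 and j < n
        if interior and (j - i) <= max_gap:
            w = np.arange(i, j)
            frac = (w - (i - 1)) / (j - (i - 1))
            filled[i:j] = (points[i - 1][None, :] * (1 - frac[:, None])
                           + points[j][None, :] * frac[:, None])
        else:
            breaks.append((i, j))
    # valid contiguous segments between unfilled runs
    segments = []
    start = 0
    for i, j in breaks:
        if i > start:
            segments.append((start, i))
        start = j
    if start < n:
        segments.append((start, n))
    return filled, segments


def reconstruct_track(pixel_tracks: np.ndarray, calibrations, fps: float,
                      max_gap: int = 3, min_frames: int = 10) -> Track3D:
    """Triangulate a multi-camera 2D beak track into a 3D path.

    Parameters
    ----------
    pixel_tracks : (n_cameras, n_frames, 2) pixels; NaN marks a missing
        detection for that camera/frame.
    calibrations : per-camera :class:`~escapeflight.calib.DLTCoefficients`.
    fps : frame rate, frames/s; frame k is at time k/fps.

    Frames with fewer than two detections are linearly interpolated in 3D
    when the gap is at most ``max_gap`` frames; longer gaps split the track
    and the longest contiguous segment is kept (flagged ``split``).  A
    longest segment shorter than ``min_frames`` raises :class:`TrackError`.
    """
    tracks = np.asarray(pixel_tracks, dtype=float)
    if tracks.ndim != 3 or tracks.shape[2] != 2:
        raise TrackError("pixel_tracks must be (n_cameras, n_frames, 2)")
    if tracks.shape[0] < 2:
        raise TrackError("need >= 2 cameras")
    points, resid = triangulate_tracks(calibrations, tracks)
    filled, segments = _fill_gaps(points, max_gap=max_gap)
    flags = []
    if not segments:
        raise TrackError("no frames with >= 2 camera views")
    if len(segments) > 1 or segments[0] != (0, len(points)):
        flags.append("split")
    start, stop = max(segments, key=lambda s: s[1] - s[0])
    if stop - start < min_frames:
        raise TrackError(
            f"longest valid segment has {stop - start} frames (< {min_frames})")
    if np.isnan(filled[start:stop]).any():
        flags.append("interpolated")
    # re-fill inside the kept segment (interpolation already applied)
    times = np.arange(start, stop) / fps
    return Track3D(times=times, positions=filled[start:stop],
                   residuals=resid[start:stop], fps=fps, qc_flags=tuple(flags))


# ---------------------------------------------------------------------------
# Kalman / RTS smoothing


def kalman_smooth(track: Track3D, process_noise: float = 1.0,
                  measurement_noise: float = 7e-4) -> SmoothedTrack:
    """Constant-velocity Kalman filter + RTS smoother, per axis.

    State per axis is (position, velocity) with white-acceleration process
    noise: ``process_noise`` is the acceleration SD in m/s^2 and
    ``measurement_noise`` the position measurement SD in metres (typically
    the triangulation error).  The covariance recursion is shared across the
    three axes (identical model), so gains are computed once.

    Returns smoothed positions and velocities at every frame.
    """
    if process_noise <= 0 or measurement_noise <= 0:
        raise TrackError("process and measurement noise must be positive")
    y = np.asarray(track.positions, dtype=float)
    n = len(y)
    if n < 3:
        raise TrackError("need >= 3 frames to smooth")
    dt = 1.0 / track.fps
    F = np.array([[1.0, dt], [0.0, 1.0]])
    q = process_noise ** 2
    Q = q * np.array([[dt ** 4 / 4, dt ** 3 / 2], [dt ** 3 / 2, dt ** 2]])
    R = measurement_noise ** 2

    # forward filter; state m has shape (2, 3) = (pos/vel, axis)
    m = np.vstack([y[0], (y[1] - y[0]) / dt])
    P = np.diag([R, (2 * R) / dt ** 2 + q * dt ** 2])
    m_filt = np.empty((n, 2, 3))
    P_filt = np.empty((n, 2, 2))
    m_pred = np.empty((n, 2, 3))
    P_pred = np.empty((n, 2, 2))
    m_filt[0], P_filt[0] = m, P
    m_pred[0], P_pred[0] = m, P
    for k in range(1, n):
        mp = F @ m
        Pp = F @ P @ F.T + Q
        S = Pp[0, 0] + R
        K = Pp[:, 0] / S                      # (2,)
        innov = y[k] - mp[0]                  # (3,)
        m = mp + K[:, None] * innov[None, :]
        P = Pp - np.outer(K, Pp[0, :])
        m_pred[k], P_pred[k] = mp, Pp
        m_filt[k], P_filt[k] = m, P

    # backward RTS pass
    m_smooth = np.empty_like(m_filt)
    m_smooth[-1] = m_filt[-1]
    for k in range(n - 2, -1, -1):
        Gk = P_filt[k] @ F.T @ np.linalg.inv(P_pred[k + 1])
        m_smooth[k] = m_filt[k] + Gk @ (m_smooth[k + 1] - m_pred[k + 1])

    return SmoothedTrack(times=track.times, positions=m_smooth[:, 0, :],
                         velocities=m_smooth[:, 1, :],
                         process_noise=process_noise,
                         measurement_noise=measurement_noise)


# ---------------------------------------------------------------------------
# summary measurements


def trajectory_average_speed(smoothed: SmoothedTrack,
                             method: str = "mean_norm") -> float:
    """Trajectory-average flight speed U.

    ``mean_norm`` (default): mean over frames of ||velocity||, i.e. the
    average instantaneous 3D speed.  ``net_displacement``: straight-line
    displacement divided by duration, exposed for comparison.
    """
    v = np.asarray(smoothed.velocities)
    if v.size == 0:
        raise TrackError("empty track")
    if method == "mean_norm":
        return float(np.mean(np.linalg.norm(v, axis=1)))
    if method == "net_displacement":
        dt = smoothed.times[-1] - smoothed.times[0]
        if dt <= 0:
            raise TrackError("zero-duration track")
        disp = smoothed.positions[-1] - smoothed.positions[0]
        return float(np.linalg.norm(disp) / dt)
    raise TrackError(f"unknown speed method {method!r}")


def wingbeat_frequency(onset_times) -> float:
    """Trajectory-average wingbeat frequency from downstroke-onset times.

    f = (n_onsets - 1) / (t_last - t_first); needs >= 2 strictly increasing
    onsets.
    """
    t = np.asarray(onset_times, dtype=float)
    if t.size < 2:
        raise TrackError(f"need >= 2 downstroke onsets, got {t.size}")
    if not np.all(np.diff(t) > 0):
        raise TrackError("onset times must be strictly increasing")
    return float((t.size - 1) / (t[-1] - t[0]))


def max_wingspan(left: Track3D, right: Track3D, onset_times=None) -> float:
    """Maximum wingspan b_max: largest simultaneous wingtip separation.

    If ``onset_times`` is given, requires the tracks to cover at least one
    full wingbeat (two consecutive downstroke onsets).
    """
    if left is None or right is None:
        raise TrackError("both wingtips must be tracked")
    if len(left.times) != len(right.times):
        raise TrackError("wingtip tracks must be simultaneous (equal length)")
    if onset_times is not None:
        t = np.asarray(onset_times, dtype=float)
        covered = (t.size >= 2 and t[0] >= left.times[0] - 1e-9
                   and t[1] <= left.times[-1] + 1e-9)
        if not covered:
            raise TrackError("wingtip coverage is shorter than one wingbeat")
    span = np.linalg.norm(left.positions - right.positions, axis=1)
    if span.size == 0 or np.all(np.isnan(span)):
        raise TrackError("no valid simultaneous wingtip frames")
    return float(np.nanmax(span))


def analyze_recording(recording, calibrations, *, process_noise: float = 1.0,
                      measurement_noise: float = 7e-4,
                      fps: float | None = None) -> FlightTrialResult:
    """Full per-flight measurement: reconstruct the beak, smooth, and reduce
    to (U, f).  ``recording`` is a synthgen SceneRecording or any object with
    the same fields."""
    fps = fps if fps is not None else 1.0 / (recording.times[1] - recording.times[0])
    track = reconstruct_track(recording.pixel_tracks["beak"], calibrations, fps)
    smoothed = kalman_smooth(track, process_noise, measurement_noise)
    speed = trajectory_average_speed(smoothed)
    flags = list(track.qc_flags)
    onsets = np.asarray(recording.downstroke_onset_frames) / fps
    if onsets.size >= 2:
        freq = wingbeat_frequency(onsets)
    else:
        freq = float("nan")
        flags.append("too_few_downstrokes")
    trial = recording.trial
    return FlightTrialResult(
        trial_id=trial.trial_id, bird_id=trial.bird_id, test_day=trial.test_day,
        flight_index=trial.flight_index, mean_speed=speed, wingbeat_freq=freq,
        n_downstrokes=int(onsets.size), body_mass_g=trial.body_mass_on_day_g,
        qc_flags=tuple(flags))
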