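"""DLT camera calibration and stereo triangulation.

The classical 11-parameter Direct Linear Transformation maps a world point
(x, y, z) in metres to a pixel (u, v)::

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)

Calibration fits L1..L11 per camera by linear least squares from >= 6
non-coplanar bead correspondences; triangulation inverts the projection
across >= 2 cameras, again as a linear least-squares problem (each camera
contributes two linear equations in x, y, z).  No lens-distortion terms and
no iterative refinement: the linear DLT is the model.

Coordinate conventions: right-handed tunnel frame, z vertical-up, origin at
the tunnel floor centre, metres; pixels (u, v) with origin top-left, v down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CalibrationError(ValueError):
    """Calibration or triangulation input is unusable (too few points,
    coplanar beads, degenerate camera geometry, point behind camera)."""


# smallest/largest singular value below this ratio => coplanar / ill-conditioned
_RANK_TOL = 1e-8


@dataclass(frozen=True)
class DLTCoefficients:
    """One camera's fitted DLT parameters L1..L11 plus fit diagnostics."""

    L: np.ndarray  # shape (11,)
    reprojection_rmse: float = 0.0
    n_points_used: int = 0
    camera_id: str = ""

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if L.shape != (11,):
            raise CalibrationError(f"expected 11 DLT coefficients, got shape {L.shape}")
        if not np.all(np.isfinite(L)):
            raise CalibrationError("non-finite DLT coefficients")
        object.__setattr__(self, "L", L)


def _check_noncoplanar(world: np.ndarray) -> None:
    centered = world - world.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < _RANK_TOL:
        raise CalibrationError(
            "calibration points are coplanar or degenerate "
            f"(singular-value ratio {0 if sv[0] == 0 else sv[-1] / sv[0]:.2e})")


def fit_dlt(world, pixels, camera_id: str = "") -> DLTCoefficients:
    """Fit the 11 DLT parameters for one camera.

    Parameters
    ----------
    world : (n, 3) array of 3D bead positions in metres, n >= 6, non-coplanar.
    pixels : (n, 2) array of the corresponding pixel observations (u, v).

    The DLT equations are linear in L once both sides are multiplied by the
    projective denominator, giving 2n equations in 11 unknowns solved by
    least squares.  Reprojection RMSE (px) is reported on the training beads.
    """
    world = np.asarray(world, dtype=float)
    pixels = np.asarray(pixels, dtype=float)
    if world.ndim != 2 or world.shape[1] != 3 or pixels.shape != (world.shape[0], 2):
        raise CalibrationError("world must be (n,3) and pixels (n,2)")
    n = world.shape[0]
    if n < 6:
        raise CalibrationError(f"need >= 6 correspondences for DLT, got {n}")
    if not (np.all(np.isfinite(world)) and np.all(np.isfinite(pixels))):
        raise CalibrationError("non-finite correspondence data")
    _check_noncoplanar(world)

    x, y, z = world.T
    u, v = pixels.T
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    A[0::2, 0:3] = world
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -u[:, None] * world
    A[1::2, 4:7] = world
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -v[:, None] * world
    b[0::2] = u
    b[1::2] = v
    L, *_ = np.linalg.lstsq(A, b, rcond=None)

    coeffs = DLTCoefficients(L=L, camera_id=camera_id, n_points_used=n)
    reproj = project(coeffs, world)
    rmse = float(np.sqrt(np.mean(np.sum((reproj - pixels) ** 2, axis=1))))
    return DLTCoefficients(L=L, reprojection_rmse=rmse, n_points_used=n,
                           camera_id=camera_id)


def project(dlt: DLTCoefficients, points) -> np.ndarray:
    """Project world point(s) through a DLT camera; returns pixels (u, v).

    Accepts a single (3,) point or an (n, 3) array.  Raises
    :class:`CalibrationError` if any point has a non-positive projective
    denominator (behind the camera).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise CalibrationError("points must have 3 coordinates")
    L = dlt.L
    denom = pts @ L[8:11] + 1.0
    if np.any(denom <= 0):
        raise CalibrationError("point behind camera (DLT denominator <= 0)")
    u = (pts @ L[0:3] + L[3]) / denom
    v = (pts @ L[4:7] + L[7]) / denom
    out = np.column_stack([u, v])
    return out[0] if np.asarray(points).ndim == 1 else out


def _ray_system(dlts, pixels):
    """Stack the 2-per-camera linear triangulation equations.

    For camera with coefficients L observing pixel (u, v):
        (L1 - u L9) x + (L2 - u L10) y + (L3 - u L11) z = u - L4
        (L5 - v L9) x + (L6 - v L10) y + (L7 - v L11) z = v - L8
    """
    k = len(dlts)
    A = np.empty((2 * k, 3))
    b = np.empty(2 * k)
    for i, (dlt, (u, v)) in enumerate(zip(dlts, pixels)):
        L = dlt.L
        A[2 * i] = L[0:3] - u * L[8:11]
        A[2 * i + 1] = L[4:7] - v * L[8:11]
        b[2 * i] = u - L[3]
        b[2 * i + 1] = v - L[7]
    return A, b


def triangulate(dlts, pixels, cond_max: float = 1e8):
    """Triangulate one 3D point from >= 2 camera views.

    Parameters
    ----------
    dlts : sequence of :class:`DLTCoefficients`, one per observing camera.
    pixels : sequence of (u, v) observations, same order.
    cond_max : reject geometries whose stacked linear system has a condition
        number above this (near-parallel rays).

    Returns
    -------
    point : (3,) world coordinates in metres.
    residuals : (k,) per-camera reprojection residual in pixels.
    """
    if len(dlts) < 2:
        raise CalibrationError(f"triangulation needs >= 2 views, got {len(dlts)}")
    if len(pixels) != len(dlts):
        raise CalibrationError("one pixel observation required per camera")
    A, b = _ray_system(dlts, pixels)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_max:
        raise CalibrationError(
            f"ill-conditioned triangulation geometry (condition number {cond:.3g})")
    point, *_ = np.linalg.lstsq(A, b, rcond=None)
    residuals = np.array([
        np.linalg.norm(project(dlt, point) - np.asarray(px, dtype=float))
        for dlt, px in zip(dlts, pixels)
    ])
    return point, residuals


def triangulate_tracks(dlts, pixel_tracks) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised triangulation of a whole track seen by the same cameras.

    Parameters
    ----------
    dlts : k cameras.
    pixel_tracks : (k, n, 2) pixel observations; frames where a camera has no
        detection are NaN and that camera is dropped for that frame.

    Returns ``(points (n, 3), mean_residual (n,))``; frames with < 2 finite
    views come back as NaN rows.

    Solves the per-frame normal equations in a single batched 3x3 solve,
    which is what makes replicate-scale simulation studies affordable.
    """
    tracks = np.asarray(pixel_tracks, dtype=float)
    k, n, _ = tracks.shape
    if k < 2:
        raise CalibrationError("triangulation needs >= 2 cameras")
    Lmat = np.stack([d.L for d in dlts])  # (k, 11)

    u = tracks[:, :, 0]  # (k, n)
    v = tracks[:, :, 1]
    # rows: (k, n, 3) coefficient blocks, one u-row and one v-row per camera
    Au = Lmat[:, None, 0:3] - u[:, :, None] * Lmat[:, None, 8:11]
    Av = Lmat[:, None, 4:7] - v[:, :, None] * Lmat[:, None, 8:11]
    bu = u - Lmat[:, None, 3]
    bv = v - Lmat[:, None, 7]

    A = np.concatenate([Au, Av], axis=0)          # (2k, n, 3)
    b = np.concatenate([bu, bv], axis=0)          # (2k, n)
    valid = np.isfinite(tracks).all(axis=2)       # (k, n)
    w = np.concatenate([valid, valid], axis=0).astype(float)  # (2k, n)
    A = np.where(w[:, :, None] > 0, A, 0.0)
    b = np.where(w > 0, b, 0.0)

    AtA = np.einsum("kni,knj->nij", A, A)         # (n, 3, 3)
    Atb = np.einsum("kni,kn->ni", A, b)           # (n, 3)
    n_views = valid.sum(axis=0)
    ok = n_views >= 2
    points = np.full((n, 3), np.nan)
    if ok.any():
        points[ok] = np.linalg.solve(AtA[ok], Atb[ok][..., None])[..., 0]

    # mean per-camera pixel residual
    denom = points @ Lmat[:, 8:11].T + 1.0        # (n, k)
    pu = (points @ Lmat[:, 0:3].T + Lmat[:, 3]) / denom
    pv = (points @ Lmat[:, 4:7].T + Lmat[:, 7]) / denom
    err = np.sqrt((pu.T - u) ** 2 + (pv.T - v) ** 2)  # (k, n)
    with np.errstate(invalid="ignore"):
        resid = np.where(ok, np.nansum(np.where(valid, err, 0.0), axis=0)
                         / np.maximum(n_views, 1), np.nan)
    return points, resid
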