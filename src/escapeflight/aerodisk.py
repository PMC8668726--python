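"""Actuator-disk model of upward flight and the tag-effect decomposition.

An upward-escaping bird must produce a thrust force at least equal to its
weight.  Actuator-disk theory models the beating wings as a circular disk of
diameter equal to the maximum wingspan ``b_max``, through which air is
accelerated downward; thrust capacity scales with disk area.  The *disk
loading* W/A — weight in Newtons per unit disk area — is therefore a proxy for
how hard upward flight is: higher loading, slower escape.

Two loadings are distinguished for a tagged bird:

* *fictive* loading, from the bird's own mass only (``W_bird / A``), and
* *real* loading, from bird plus tag (``W_bird+tag / A``).

The tag-effect decomposition splits the speed cost of tagging into a
mass-independent offset (harness, drag, "discomfort") and a component linear
in the tag-induced increase in disk loading::

    dU = dU_tag + (dU/d(W/A)) * dW_tag/A
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: gravitational acceleration, m/s^2
G = 9.81


class AerodiskError(ValueError):
    """Invalid input to an actuator-disk computation."""


def disk_area(b_max: float) -> float:
    """Actuator disk area A = pi * b_max^2 / 4 for wingspan ``b_max`` (m)."""
    if not np.all(np.asarray(b_max) > 0):
        raise AerodiskError(f"wingspan must be positive, got {b_max}")
    return np.pi * np.square(b_max) / 4.0


def disk_loading(mass_total_kg, b_max):
    """Disk loading W/A = 4 m g / (pi b_max^2) in N/m^2.

    ``mass_total_kg`` is the total supported mass (bird, or bird + tag) in kg.
    Accepts scalars or arrays.
    """
    m = np.asarray(mass_total_kg, dtype=float)
    b = np.asarray(b_max, dtype=float)
    if not (np.all(m > 0) and np.all(b > 0)):
        raise AerodiskError("mass and wingspan must be positive")
    out = 4.0 * m * G / (np.pi * np.square(b))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TagEffectModel:
    """Additive decomposition of the tagging effect on escape-flight speed.

    Both coefficients are stored as signed (negative) speed changes:

    tag_offset
        mass-independent speed change of carrying any tag, m/s.
    loading_slope
        dU/d(W/A), speed change per unit added disk loading, m^2 s/kg.
    reference_loading
        disk loading of the reference (untagged) bird, N/m^2.
    reference_speed_tagfree
        escape speed of the reference bird before tagging, m/s.
    """

    tag_offset: float = -0.11
    loading_slope: float = -0.11
    reference_loading: float = 18.0
    reference_speed_tagfree: float = 3.10

    def __post_init__(self):
        for name in ("tag_offset", "loading_slope", "reference_loading",
                     "reference_speed_tagfree"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise AerodiskError(f"model coefficient {name!r} missing or non-finite")


def predict_speed_reduction(model: TagEffectModel, loading: float,
                            tag_frac: float) -> tuple[float, float]:
    """Predict the speed change from tagging a bird of given disk loading.

    ``tag_frac`` is the tag mass as a fraction of body mass; at fixed
    wingspan the tag adds ``tag_frac * loading`` to the disk loading.

    Returns ``(dU, U_tagged)`` where ``dU`` (negative) is the predicted speed
    change and ``U_tagged = reference_speed_tagfree + dU``.
    """
    if loading <= 0:
        raise AerodiskError("disk loading must be positive")
    if not 0 <= tag_frac < 1:
        raise AerodiskError("tag mass fraction must be in [0, 1)")
    d_loading = tag_frac * loading
    du = model.tag_offset + model.loading_slope * d_loading
    return du, model.reference_speed_tagfree + du


def loading_slope_to_per_gram(loading_slope: float, area_m2: float) -> float:
    """Convert a dU/d(W/A) slope (m^2 s/kg) to dU/dm in m/s per gram.

    At fixed wingspan, one gram of added mass raises the loading by
    ``g * 1e-3 / A`` N/m^2, so dU/dm = slope * g / A * 1e-3.
    """
    if area_m2 <= 0:
        raise AerodiskError("disk area must be positive")
    return loading_slope * G / area_m2 * 1e-3


def percent_reduction(du_component: float, reference_speed: float) -> float:
    """Magnitude of a speed-change component as a percent of a reference speed."""
    if reference_speed <= 0:
        raise AerodiskError("reference speed must be positive")
    return 100.0 * abs(du_component) / reference_speed


def report_percent(percent: float) -> int:
    """Round a percentage to integer, half away from zero (reporting rule)."""
    return int(math.floor(abs(percent) + 0.5)) * (1 if percent >= 0 else -1)


def build_loading_records(cohort: pd.DataFrame,
                          flights: pd.DataFrame) -> pd.DataFrame:
    """Per-flight disk-loading table from a cohort table and flight results.

    ``cohort`` needs columns bird_id, tag_mass_g, bmax_m; ``flights`` needs
    bird_id, test_day, body_mass_g.  Returns one row per flight with weights
    (N), disk area (m^2) and fictive/real loadings (N/m^2).
    """
    merged = flights.merge(
        cohort[["bird_id", "tag_mass_g", "bmax_m"]], on="bird_id", how="left",
        validate="many_to_one")
    if merged["bmax_m"].isna().any():
        missing = merged.loc[merged["bmax_m"].isna(), "bird_id"].unique()
        raise AerodiskError(f"birds missing from cohort table: {list(missing)}")
    area = disk_area(merged["bmax_m"].to_numpy())
    w_bird = merged["body_mass_g"].to_numpy() * 1e-3 * G
    w_total = (merged["body_mass_g"] + merged["tag_mass_g"]).to_numpy() * 1e-3 * G
    out = merged.copy()
    out["disk_area_m2"] = area
    out["w_bird_n"] = w_bird
    out["w_bird_tag_n"] = w_total
    out["loading_fictive"] = w_bird / area
    out["loading_real"] = w_total / area
    return out
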