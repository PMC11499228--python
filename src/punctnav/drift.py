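"""Quantifying pre/intra/post-operative image drift and mismatch.

Drift between two registered surfaces is measured by the distance test
function: per-point nearest-surface distances of the moving model against
the reference, summarised as RMS, mean, SD and maximum. Skeletal drift is
measured residual to the surface-derived registration: the preoperative
bone model is carried through the transform obtained by registering the
*surfaces*, and its remaining distance to the postoperative bone model is
the drift attributable to bone motion relative to the fixed surface.

Cohort statistics follow the reporting convention of the cadaver study the
package models: mean ± sample standard deviation (n-1 denominator),
displayed at 3 decimals with half-away-from-zero rounding. The 20-specimen
benchmark table of registration RMS and drift values ships with the
package (``load_reference_table``).

Note that nearest-surface distance is a one-sided, correspondence-free
metric: where a surface slides tangentially along itself (a cylinder
translated across its axis, say) the per-point distances under-report the
true displacement, so the *mean* of a drift field is a lower bound on the
physical shift except on locally planar regions normal to the motion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Union

import numpy as np
from scipy import stats

from .geometry import (
    GeometryError,
    PointCloud,
    RigidTransform,
    TriMesh,
    apply_transform,
    nearest_distances,
)
from .io import write_mesh_ply

__all__ = [
    "DriftReport",
    "CohortSummary",
    "drift_field",
    "skeletal_drift",
    "cohort_summary",
    "paired_difference",
    "one_sample_t",
    "export_heatmap",
    "load_reference_table",
    "round3",
]


def round3(x: float) -> float:
    """Display rounding: 3 decimals, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass
class DriftReport:
    """Per-point drift distances (mm) with summary statistics."""

    distances: np.ndarray
    rms: float
    mean: float
    sd: float
    max: float
    source_label: str = ""
    target_label: str = ""

    def to_dict(self) -> dict:
        return {
            "rms_mm": float(self.rms),
            "mean_mm": float(self.mean),
            "sd_mm": float(self.sd),
            "max_mm": float(self.max),
            "n_points": int(len(self.distances)),
            "source": self.source_label,
            "target": self.target_label,
        }


@dataclass
class CohortSummary:
    """Mean ± sample SD (n-1) of a list of per-specimen values."""

    n: int
    mean: float
    sd: float

    def display(self) -> str:
        return f"{round3(self.mean):.3f} ± {round3(self.sd):.3f}"


def drift_field(
    moving: Union[TriMesh, PointCloud],
    reference: TriMesh,
    t: Optional[RigidTransform] = None,
    source_label: str = "",
    target_label: str = "",
) -> DriftReport:
    """Distance field of ``moving`` (after transform ``t``) against ``reference``."""
    if t is None:
        t = RigidTransform.identity()
    moved = apply_transform(moving, t)
    pts = moved.vertices if isinstance(moved, TriMesh) else moved.points
    d = nearest_distances(pts, reference)
    return DriftReport(
        distances=d,
        rms=float(np.sqrt(np.mean(d**2))),
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        max=float(np.max(d)),
        source_label=source_label,
        target_label=target_label,
    )


def skeletal_drift(
    pre_bone: TriMesh,
    post_bone: TriMesh,
    surface_alignment: RigidTransform,
) -> DriftReport:
    """Bone drift residual to the surface registration.

    The preoperative skeleton is moved by the transform obtained from
    registering the *surfaces*; whatever distance remains to the
    postoperative skeleton is drift of the bone relative to the immobilised
    surface.
    """
    if len(pre_bone) == 0 or len(post_bone) == 0:
        raise GeometryError("bone meshes must be non-empty")
    return drift_field(
        pre_bone,
        post_bone,
        surface_alignment,
        source_label="preoperative skeleton (surface-aligned)",
        target_label="postoperative skeleton",
    )


def cohort_summary(values) -> CohortSummary:
    """Mean ± sample standard deviation of per-specimen values."""
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 2:
        raise GeometryError("need at least 2 values for a cohort summary")
    return CohortSummary(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def paired_difference(a, b):
    """Cohort summary of the element-wise differences ``a_i - b_i``.

    Returns ``(CohortSummary, t_statistic, p_value)``; the t statistic is
    the paired one-sample t against zero with n-1 degrees of freedom, or
    None when the differences have zero variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise GeometryError("paired lists must have equal length")
    if len(a) < 2:
        raise GeometryError("need at least 2 pairs")
    diff = a - b
    summ = cohort_summary(diff)
    if summ.sd == 0.0:
        return summ, None, None
    t = summ.mean / (summ.sd / np.sqrt(summ.n))
    p = 2.0 * stats.t.sf(abs(t), df=summ.n - 1)
    return summ, float(t), float(p)


def one_sample_t(values):
    """One-sample t statistic and two-sided p-value against a zero mean."""
    summ = cohort_summary(values)
    if summ.sd == 0.0:
        return summ, None, None
    t = summ.mean / (summ.sd / np.sqrt(summ.n))
    p = 2.0 * stats.t.sf(abs(t), df=summ.n - 1)
    return summ, float(t), float(p)


def export_heatmap(
    mesh: TriMesh,
    distances,
    path,
    vmin: float = 0.0,
    vmax: float = 1.0,
    cmap: str = "jet",
) -> None:
    """Write a PLY heat map: per-vertex quality plus an 8-bit colour ramp.

    Distances are clamped to ``[vmin, vmax]`` for the colour mapping only;
    the quality property stores the raw values and round-trips losslessly.
    """
    distances = np.asarray(distances, dtype=float).ravel()
    if len(distances) != len(mesh.vertices):
        raise GeometryError("distance count must equal vertex count")
    if not vmax > vmin:
        raise GeometryError("vmax must exceed vmin")
    import matplotlib

    ramp = matplotlib.colormaps[cmap]
    frac = np.clip((distances - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = ramp(frac)
    colors = (rgba[:, :3] * 255).round().astype(np.uint8)
    write_mesh_ply(mesh, path, quality=distances, colors=colors)


def load_reference_table():
    """The 20-specimen benchmark table of RMS and drift values (mm).

    Columns: ``specimen`` (int), ``rms_ct_sli`` (preoperative CT vs.
    intraoperative SLI RMS), ``rms_ct_ct`` (preoperative vs. postoperative
    CT RMS), ``surface_drift``, ``skeletal_drift``. Returns a dict of numpy
    arrays.
    """
    with resources.files("punctnav.data").joinpath("specimen_benchmark.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    out = {"specimen": np.array([int(r["specimen"]) for r in rows])}
    for col in ("rms_ct_sli", "rms_ct_ct", "surface_drift", "skeletal_drift"):
        out[col] = np.array([float(r[col]) for r in rows])
    return out
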