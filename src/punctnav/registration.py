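"""Coarse-to-fine rigid registration of intraoperative surface scans to CT models.

The intraoperative structured-light cloud is aligned to the preoperative CT
surface model in two steps: a coarse landmark (feature-match) alignment
solved in closed form by the Kabsch/SVD method, then fine alignment by a
trimmed, subsampled iterative-closest-point refinement against the mesh.
The resulting transform maps CT coordinates into the scanner frame
(``M_SLI = R * M_CT + T``); the total transform is the exact composition of
the coarse and fine steps.

Registration quality is gated by the distance test function: the RMS of
nearest-surface distances from the full (non-subsampled) cloud to the
transformed CT model. If the RMS exceeds the quality threshold the fine
step is restarted with a fresh subsample seed, up to ``max_restarts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    GeometryError,
    PointCloud,
    RigidTransform,
    TriMesh,
    apply_transform,
    build_distance_query,
    compose_transforms,
    invert_transform,
    nearest_points,
)

__all__ = [
    "IcpParams",
    "RegistrationResult",
    "NoCorrespondenceError",
    "DegenerateLandmarkError",
    "coarse_align",
    "icp_refine",
    "register_two_step",
    "crop_and_denoise",
]


class DegenerateLandmarkError(GeometryError):
    """Fewer than 3 landmark pairs, or a collinear configuration."""


class NoCorrespondenceError(GeometryError):
    """Every candidate correspondence was rejected by the gating rules."""


@dataclass
class IcpParams:
    """Tuning knobs of the speed-up ICP refinement.

    subsample_size: number of source points used for the iteration (the
        full cloud is still used for the final quality RMS);
    trim_fraction: fraction of the largest-distance correspondences dropped
        each iteration (robustness to partial overlap and outliers);
    max_pair_distance: optional hard correspondence gate in mm;
    rel_tolerance: relative RMS change that stops the iteration.
    """

    max_iterations: int = 100
    rel_tolerance: float = 1e-6
    subsample_size: int = 5000
    trim_fraction: float = 0.2
    max_pair_distance: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 1:
            raise GeometryError("trim_fraction must be in [0, 1)")
        if self.subsample_size < 3:
            raise GeometryError("subsample_size must be >= 3")
        if self.max_iterations < 1:
            raise GeometryError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Outcome of (coarse, fine) registration.

    ``total`` is always the exact composition coarse-then-fine. ``rms`` is
    the quality metric the result was gated on; ``rms_trace`` holds the
    per-iteration trimmed RMS of the ICP refinement.
    """

    coarse: RigidTransform
    fine: RigidTransform
    total: RigidTransform
    rms: float
    iterations: int
    converged: bool
    rms_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_dict(self) -> dict:
        return {
            "coarse": {"rotation": self.coarse.rotation.tolist(),
                       "translation": self.coarse.translation.tolist()},
            "fine": {"rotation": self.fine.rotation.tolist(),
                     "translation": self.fine.translation.tolist()},
            "total": {"rotation": self.total.rotation.tolist(),
                      "translation": self.total.translation.tolist()},
            "rms": float(self.rms),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "rms_trace": [float(x) for x in self.rms_trace],
        }


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (proper rotation)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cd - rot @ cs)


def coarse_align(src_landmarks, dst_landmarks) -> RigidTransform:
    """Closed-form rigid alignment from paired landmark correspondences.

    Minimises the sum of squared residuals over >= 3 non-collinear pairs
    (centroid alignment + SVD with determinant correction).
    """
    src = np.asarray(src_landmarks, dtype=float)
    dst = np.asarray(dst_landmarks, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != dst.shape:
        raise DegenerateLandmarkError("landmark lists must both be (N, 3)")
    if len(src) < 3:
        raise DegenerateLandmarkError("need at least 3 landmark pairs")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateLandmarkError("landmarks are collinear; rotation is ambiguous")
    return _kabsch(src, dst)


def icp_refine(
    src: PointCloud,
    dst: Union[PointCloud, TriMesh],
    init: RigidTransform,
    p: IcpParams = IcpParams(),
) -> RegistrationResult:
    """Trimmed, subsampled point-to-point ICP refinement.

    A random subsample of the source (drawn once per run from ``p.seed``) is
    iteratively matched to its nearest points on the target; the
    ``trim_fraction`` largest-distance pairs (and any beyond
    ``max_pair_distance``) are dropped; the rigid update is solved in closed
    form. Stops when the trimmed RMS changes by less than ``rel_tolerance``
    (relatively) or after ``max_iterations``. The returned ``fine``
    transform is the cumulative correction applied after ``init``.
    """
    pts = src.points
    if len(pts) < 3:
        raise GeometryError("source cloud must have at least 3 points")
    rng = np.random.default_rng(p.seed)
    if len(pts) > p.subsample_size:
        idx = rng.choice(len(pts), size=p.subsample_size, replace=False)
        sub = pts[idx]
    else:
        sub = pts

    n = len(sub)
    keep = max(3, int(np.ceil((1.0 - p.trim_fraction) * n)))
    fine = RigidTransform.identity()
    current = init
    trace = []
    prev_rms = None
    converged = False
    iterations = 0
    dst_query = build_distance_query(dst) if isinstance(dst, (PointCloud, TriMesh)) else dst

    for _ in range(p.max_iterations):
        iterations += 1
        q = current.apply(sub)
        d, targets = nearest_points(q, dst_query)
        order = np.argsort(d)
        sel = order[:keep]
        if p.max_pair_distance is not None:
            sel = sel[d[sel] <= p.max_pair_distance]
        if len(sel) < 3:
            raise NoCorrespondenceError(
                "fewer than 3 correspondences survive the distance gates"
            )
        rms = float(np.sqrt(np.mean(d[sel] ** 2)))
        trace.append(rms)
        if rms < 1e-9:  # machine-zero alignment; nothing left to refine
            converged = True
            break
        if prev_rms is not None and abs(prev_rms - rms) <= p.rel_tolerance * max(prev_rms, 1e-12):
            converged = True
            break
        prev_rms = rms
        delta = _kabsch(q[sel], targets[sel])
        current = compose_transforms(current, delta)
        fine = compose_transforms(fine, delta)

    return RegistrationResult(
        coarse=init,
        fine=fine,
        total=compose_transforms(init, fine),
        rms=trace[-1],
        iterations=iterations,
        converged=converged,
        rms_trace=np.asarray(trace),
    )


def register_two_step(
    sli: PointCloud,
    ct_surface: TriMesh,
    landmarks,
    p: IcpParams = IcpParams(),
    quality_threshold: float = 1.0,
    max_restarts: int = 3,
) -> RegistrationResult:
    """Coarse landmark alignment followed by ICP refinement, quality gated.

    ``landmarks`` is a pair ``(ct_points, sli_points)`` of corresponding
    feature coordinates (the conspicuous bandage-fixture features). The
    returned transforms map CT coordinates to SLI coordinates. Quality is
    the RMS of nearest-surface distances from the *full* cloud to the
    transformed CT model; if above ``quality_threshold`` the ICP is
    restarted with a new subsample seed, up to ``max_restarts`` extra
    attempts, and the best result is returned with ``converged`` set to
    whether the threshold was met.
    """
    ct_lms, sli_lms = landmarks
    ct_lms = np.asarray(ct_lms, dtype=float)
    sli_lms = np.asarray(sli_lms, dtype=float)
    if ct_lms.shape != sli_lms.shape:
        raise DegenerateLandmarkError("landmark lists have unequal length")
    coarse = coarse_align(ct_lms, sli_lms)  # CT -> SLI

    # ICP moves the SLI cloud onto the coarse-transformed CT mesh; the fine
    # CT->SLI correction is the inverse of that motion.
    mesh_c = apply_transform(ct_surface, coarse)
    mesh_query = build_distance_query(mesh_c)
    best = None
    for attempt in range(max_restarts + 1):
        params = IcpParams(
            max_iterations=p.max_iterations,
            rel_tolerance=p.rel_tolerance,
            subsample_size=p.subsample_size,
            trim_fraction=p.trim_fraction,
            max_pair_distance=p.max_pair_distance,
            seed=p.seed + attempt,
        )
        res = icp_refine(sli, mesh_query, RigidTransform.identity(), params)
        fine = invert_transform(res.fine)
        total = compose_transforms(coarse, fine)
        # rigid motions preserve distances, so the quality RMS of the cloud
        # against total(CT) equals that of fine^-1(cloud) against coarse(CT)
        d, _ = nearest_points(res.fine.apply(sli.points), mesh_query)
        rms = float(np.sqrt(np.mean(d**2)))
        cand = RegistrationResult(
            coarse=coarse,
            fine=fine,
            total=total,
            rms=rms,
            iterations=res.iterations,
            converged=rms <= quality_threshold,
            rms_trace=res.rms_trace,
        )
        if best is None or cand.rms < best.rms:
            best = cand
        if cand.converged:
            break
    return best


def crop_and_denoise(
    cloud: PointCloud,
    box=None,
    nn_k: int = 8,
    sigma_factor: float = 2.0,
) -> PointCloud:
    """Axis-aligned crop followed by statistical outlier removal.

    ``box`` is ``(min_corner, max_corner)`` in mm, or None to skip cropping.
    A point survives denoising when its mean distance to its ``nn_k``
    nearest neighbours is within ``mean + sigma_factor * SD`` of that
    statistic's distribution over the cropped cloud.
    """
    if len(cloud) == 0:
        raise GeometryError("cannot crop an empty cloud")
    kept = cloud
    if box is not None:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
        mask = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
        if not mask.any():
            raise GeometryError("crop box excludes every point")
        kept = cloud.select(mask)
    if len(kept) <= nn_k:
        return kept
    tree = cKDTree(kept.points)
    d, _ = tree.query(kept.points, k=nn_k + 1)  # first neighbour is the point itself
    mean_d = d[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + sigma_factor * mean_d.std()
    return kept.select(mean_d <= cutoff)
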