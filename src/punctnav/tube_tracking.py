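"""RANSAC cylinder tracking of the puncture guiding tube.

The structured-light camera sees a partial, noisy strip of the guiding
tube's surface (roughly half its circumference). A cylinder is fitted to
that cloud by RANSAC: each hypothesis is generated from two points with
estimated normals (the cylinder axis is perpendicular to both surface
normals, so the axis direction is their cross product), inliers are points
whose distance to the axis is within ``distance_threshold`` of the
candidate radius, and the best consensus model is polished by non-linear
least squares over its inliers. The fitted axis is then scored against the
planned puncture path (angle, lateral offset, tip gap) to give the surgeon
real-time feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import (
    CylinderModel,
    GeometryError,
    PointCloud,
    PuncturePath,
    TriMesh,
)

__all__ = [
    "RansacParams",
    "PathDeviation",
    "CylinderFitError",
    "estimate_normals",
    "fit_cylinder_ransac",
    "path_deviation",
    "check_tolerance",
    "cylinder_mesh",
]


class CylinderFitError(GeometryError):
    """No cylinder hypothesis reached the required inlier consensus."""


@dataclass
class RansacParams:
    distance_threshold: float = 0.6
    max_iterations: int = 1000
    min_inlier_fraction: float = 0.25
    normal_k: int = 12
    seed: int = 0

    def __post_init__(self):
        if not self.distance_threshold > 0:
            raise GeometryError("distance_threshold must be > 0")
        if self.max_iterations < 1:
            raise GeometryError("max_iterations must be >= 1")
        if not 0 <= self.min_inlier_fraction <= 1:
            raise GeometryError("min_inlier_fraction must be in [0, 1]")


@dataclass
class PathDeviation:
    """Alignment of the fitted tube against the planned trajectory.

    angle: degrees between tube axis and planned direction (orientation
        agnostic, in [0, 90]);
    lateral_offset: mm distance from the planned entry point to the tube
        axis treated as an infinite line;
    tip_gap: mm distance from the tube end nearer the entry point to the
        entry point.
    """

    angle: float
    lateral_offset: float
    tip_gap: float

    def to_dict(self) -> dict:
        return {
            "angle_deg": float(self.angle),
            "lateral_offset_mm": float(self.lateral_offset),
            "tip_gap_mm": float(self.tip_gap),
        }


def estimate_normals(cloud: PointCloud, k: int = 12, viewpoint=None) -> PointCloud:
    """Per-point normals from k-nearest-neighbour PCA.

    The normal is the smallest-eigenvalue eigenvector of the neighbourhood
    covariance. Signs are oriented toward ``viewpoint`` if given, otherwise
    outward from the cloud centroid.
    """
    if k < 3:
        raise GeometryError("k must be >= 3")
    pts = cloud.points
    if len(pts) < k + 1:
        raise GeometryError(f"cloud has {len(pts)} points; need at least k+1 = {k + 1}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)  # includes the point itself
    nbrs = pts[idx]  # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    ref = (np.asarray(viewpoint, dtype=float) - pts) if viewpoint is not None \
        else (pts - pts.mean(axis=0))
    flip = np.einsum("ij,ij->i", normals, ref) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts.copy(), normals, cloud.scalars)


def _point_line_distance(points: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    """Distances from points to the infinite line (origin, unit direction)."""
    rel = points - origin
    return np.linalg.norm(np.cross(rel, direction), axis=1)


def _two_point_hypothesis(p1, n1, p2, n2):
    """Cylinder (axis point, axis dir, radius) from two oriented points.

    The axis is perpendicular to both surface normals; the axis point is
    the midpoint of the common perpendicular of the two normal lines.
    Returns None for (near-)parallel normals.
    """
    w = np.cross(n1, n2)
    nw = np.linalg.norm(w)
    if nw < 1e-6:
        return None
    w = w / nw
    # closest points between lines p1 + t*n1 and p2 + s*n2
    b = n1 @ n2
    d = p2 - p1
    denom = 1.0 - b * b
    t = (d @ n1 - b * (d @ n2)) / denom
    s = (b * (d @ n1) - d @ n2) / denom
    a1 = p1 + t * n1
    a2 = p2 + s * n2
    axis_point = 0.5 * (a1 + a2)
    radius = 0.5 * (
        _point_line_distance(p1[None], axis_point, w)[0]
        + _point_line_distance(p2[None], axis_point, w)[0]
    )
    if radius < 1e-9:
        return None
    return axis_point, w, radius


def _orthonormal_basis(w: np.ndarray):
    """Two unit vectors completing ``w`` to a right-handed frame."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def _refine_cylinder(points: np.ndarray, axis_point, axis_dir, radius):
    """Least-squares polish of (axis, radius) over the given points.

    Parametrisation: axis point offsets in the plane perpendicular to the
    current axis, two small axis tilt angles, and the radius.
    """
    u, v = _orthonormal_basis(axis_dir)

    def unpack(x):
        a = axis_point + x[0] * u + x[1] * v
        w = axis_dir + x[2] * u + x[3] * v
        w = w / np.linalg.norm(w)
        return a, w, x[4]

    def residuals(x):
        a, w, r = unpack(x)
        return _point_line_distance(points, a, w) - r

    x0 = np.array([0.0, 0.0, 0.0, 0.0, radius])
    sol = least_squares(residuals, x0, method="lm", max_nfev=200)
    return unpack(sol.x)


def fit_cylinder_ransac(cloud: PointCloud, p: RansacParams = RansacParams()):
    """RANSAC cylinder fit returning ``(CylinderModel, inlier_flags)``.

    Normals are estimated with ``p.normal_k`` neighbours if absent. Inliers
    of the refined model are re-scored against it, so the returned flags are
    exactly reproducible from the returned model and threshold.
    """
    if len(cloud) < 2:
        raise GeometryError("need at least 2 points to fit a cylinder")
    if cloud.normals is None:
        cloud = estimate_normals(cloud, k=p.normal_k)
    pts = cloud.points
    nrm = cloud.normals
    n = len(pts)
    rng = np.random.default_rng(p.seed)

    best_count = 0
    best = None
    for _ in range(p.max_iterations):
        i, j = rng.choice(n, size=2, replace=False)
        hyp = _two_point_hypothesis(pts[i], nrm[i], pts[j], nrm[j])
        if hyp is None:
            continue
        a, w, r = hyp
        resid = np.abs(_point_line_distance(pts, a, w) - r)
        count = int((resid <= p.distance_threshold).sum())
        if count > best_count:
            best_count = count
            best = (a, w, r)

    if best is None or best_count / n < p.min_inlier_fraction:
        raise CylinderFitError(
            f"best consensus {best_count}/{n} below min_inlier_fraction "
            f"{p.min_inlier_fraction}"
        )

    a, w, r = best
    inliers = np.abs(_point_line_distance(pts, a, w) - r) <= p.distance_threshold
    a, w, r = _refine_cylinder(pts[inliers], a, w, r)
    # final flags are scored against the refined model
    inliers = np.abs(_point_line_distance(pts, a, w) - r) <= p.distance_threshold
    if inliers.sum() / n < p.min_inlier_fraction:
        raise CylinderFitError("refined model lost its inlier consensus")

    proj = (pts[inliers] - a) @ w
    t_lo, t_hi = float(proj.min()), float(proj.max())
    length = t_hi - t_lo
    center = a + 0.5 * (t_lo + t_hi) * w
    model = CylinderModel(center=center, axis=w, radius=float(r), length=length)
    return model, inliers


def path_deviation(tube: CylinderModel, path: PuncturePath) -> PathDeviation:
    """Angle, lateral offset and tip gap between fitted tube and planned path."""
    cosang = abs(float(tube.axis @ path.direction))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    lateral = float(_point_line_distance(path.entry[None], tube.center, tube.axis)[0])
    ends = tube.endpoints
    gaps = np.linalg.norm(ends - path.entry, axis=1)
    return PathDeviation(angle=angle, lateral_offset=lateral, tip_gap=float(gaps.min()))


def check_tolerance(dev: PathDeviation, max_angle: float = 3.0, max_offset: float = 2.0):
    """Pass/fail gate for tube placement; thresholds are inclusive.

    Returns ``(passed, message)``; the message names every violated quantity.
    """
    if not (max_angle > 0 and max_offset > 0):
        raise GeometryError("tolerances must be > 0")
    violations = []
    if dev.angle > max_angle:
        violations.append(f"angle {dev.angle:.3f} deg exceeds {max_angle:.3f} deg")
    if dev.lateral_offset > max_offset:
        violations.append(
            f"lateral_offset {dev.lateral_offset:.3f} mm exceeds {max_offset:.3f} mm"
        )
    if violations:
        return False, "; ".join(violations)
    return True, "within tolerance"


def cylinder_mesh(obj, radius: float | None = None, sections: int = 48) -> TriMesh:
    """Visualisation mesh for a fitted tube or a planned path.

    A PuncturePath is rendered as a thin cylinder of the given radius
    (default 1 mm) spanning entry to target.
    """
    import trimesh

    if isinstance(obj, CylinderModel):
        center, axis, r, length = obj.center, obj.axis, obj.radius, obj.length
    elif isinstance(obj, PuncturePath):
        center = obj.entry + 0.5 * obj.depth * obj.direction
        axis, r, length = obj.direction, (radius or 1.0), obj.depth
    else:
        raise GeometryError("expected a CylinderModel or PuncturePath")
    tm = trimesh.creation.cylinder(radius=r, height=length, sections=sections)
    z = np.array([0.0, 0.0, 1.0])
    rot = trimesh.geometry.align_vectors(z, axis)
    tm.apply_transform(rot)
    tm.apply_translation(center)
    return TriMesh.from_trimesh(tm)
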