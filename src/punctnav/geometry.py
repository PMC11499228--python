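"""Shared geometric types and primitives for the navigation pipeline.

All coordinates are in millimetres, in a right-handed world frame. Rigid
transforms map points as ``p' = R p + t`` with a proper rotation ``R``
(the convention of the surface-to-CT mapping ``M_SLI = R * M_CT + T`` used
throughout the registration stage).

Nearest-distance queries are exact: point-to-cloud uses a KD-tree, and
point-to-mesh combines a KD-tree candidate search over triangle centroids
with an exact closest-point-on-triangle computation and a conservative
radius bound, so the result equals the brute-force minimum over all
triangles. Sub-millimetre drift metrics cannot tolerate approximate
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "TransformValidityError",
    "PointCloud",
    "TriMesh",
    "RigidTransform",
    "Volume",
    "CylinderModel",
    "PuncturePath",
    "apply_transform",
    "compose_transforms",
    "invert_transform",
    "nearest_distances",
    "nearest_points",
    "build_distance_query",
    "rotation_about_axis",
]

_ORTHO_TOL = 1e-8


class GeometryError(ValueError):
    """Invalid geometric input (empty cloud, bad indices, ...)."""


class TransformValidityError(GeometryError):
    """Rotation fails the orthonormality / proper-rotation invariants."""


def _as_points(a, name="points") -> np.ndarray:
    pts = np.asarray(a, dtype=float)
    if pts.ndim == 1 and pts.size == 3:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"{name} must be an (N, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise GeometryError(f"{name} contains non-finite coordinates")
    return pts


@dataclass
class PointCloud:
    """Unordered 3D points (mm) with optional unit normals and per-point scalars."""

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    scalars: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = _as_points(self.points)
        n = len(self.points)
        if self.normals is not None:
            self.normals = _as_points(self.normals, "normals")
            if len(self.normals) != n:
                raise GeometryError("normal count must equal point count")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise GeometryError("normals must have unit length (within 1e-6)")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).ravel()
            if len(self.scalars) != n:
                raise GeometryError("scalar count must equal point count")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_indices) -> "PointCloud":
        """Subset of the cloud, carrying normals/scalars through."""
        return PointCloud(
            self.points[mask_or_indices],
            None if self.normals is None else self.normals[mask_or_indices],
            None if self.scalars is None else self.scalars[mask_or_indices],
        )


@dataclass
class TriMesh:
    """Triangulated surface: vertices (mm) and 0-based vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (M, 3) integer array")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise GeometryError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise GeometryError("degenerate face repeats a vertex index")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def triangles(self) -> np.ndarray:
        """(M, 3, 3) triangle vertex coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise TransformValidityError("rotation must be 3x3, translation length 3")
        r = self.rotation
        if np.linalg.norm(r.T @ r - np.eye(3)) > _ORTHO_TOL:
            raise TransformValidityError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > _ORTHO_TOL:
            raise TransformValidityError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class Volume:
    """3D scalar grid in Hounsfield units with voxel-center world mapping.

    World position of voxel index (i, j, k) is ``origin + index * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise GeometryError("volume values must be a non-empty 3D grid")
        self.spacing = np.asarray(self.spacing, dtype=float).ravel()
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise GeometryError("spacing and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise GeometryError("all spacing components must be > 0")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class CylinderModel:
    """Fitted guiding tube: axis-segment midpoint, unit axis, radius, length (mm)."""

    center: np.ndarray
    axis: np.ndarray
    radius: float
    length: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).ravel()
        self.axis = np.asarray(self.axis, dtype=float).ravel()
        if self.center.shape != (3,) or self.axis.shape != (3,):
            raise GeometryError("center and axis must be 3-vectors")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-8:
            raise GeometryError("axis must be unit length")
        if not self.radius > 0:
            raise GeometryError("radius must be > 0")
        if not self.length > 0:
            raise GeometryError("length must be > 0")

    @property
    def endpoints(self) -> np.ndarray:
        h = 0.5 * self.length
        return np.array([self.center - h * self.axis, self.center + h * self.axis])


@dataclass
class PuncturePath:
    """Planned trajectory: skin entry point, unit direction toward target, depth (mm)."""

    entry: np.ndarray
    direction: np.ndarray
    depth: float

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float).ravel()
        self.direction = np.asarray(self.direction, dtype=float).ravel()
        if self.entry.shape != (3,) or self.direction.shape != (3,):
            raise GeometryError("entry and direction must be 3-vectors")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-8:
            raise GeometryError("direction must be unit length")
        if not self.depth > 0:
            raise GeometryError("depth must be > 0")

    @property
    def target(self) -> np.ndarray:
        return self.entry + self.depth * self.direction


Model = Union[PointCloud, TriMesh]


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float).ravel()
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def apply_transform(model: Model, t: RigidTransform) -> Model:
    """Map a cloud or mesh through a rigid transform.

    Normals are rotated only; faces and scalars are carried over.
    """
    if not isinstance(t, RigidTransform):
        raise TransformValidityError("t must be a RigidTransform")
    if isinstance(model, PointCloud):
        if len(model) == 0:
            raise GeometryError("cannot transform an empty cloud")
        normals = None if model.normals is None else model.normals @ t.rotation.T
        return PointCloud(t.apply(model.points), normals, model.scalars)
    if isinstance(model, TriMesh):
        if len(model) == 0:
            raise GeometryError("cannot transform an empty mesh")
        return TriMesh(t.apply(model.vertices), model.faces.copy())
    raise GeometryError(f"unsupported model type: {type(model)!r}")


def compose_transforms(
    first: RigidTransform, second: RigidTransform, mode: str = "exact"
) -> RigidTransform:
    """Composition g with ``g(p) = second(first(p))``.

    ``mode="exact"`` (default) uses the mathematically exact rule
    ``R = R2 R1, T = R2 T1 + T2``. ``mode="legacy"`` reproduces the additive
    translation convention ``T = T1 + T2`` sometimes quoted for coarse+fine
    registration chains; it agrees with the exact rule only when the second
    rotation is the identity (e.g. a fine step that is a pure translation).
    """
    rot = second.rotation @ first.rotation
    if mode == "exact":
        trans = second.rotation @ first.translation + second.translation
    elif mode == "legacy":
        trans = first.translation + second.translation
    else:
        raise ValueError(f"unknown composition mode: {mode!r}")
    return RigidTransform(rot, trans)


def invert_transform(t: RigidTransform) -> RigidTransform:
    """Inverse motion: ``compose(t, invert(t))`` is the identity."""
    rinv = t.rotation.T
    return RigidTransform(rinv, -rinv @ t.translation)


# ---------------------------------------------------------------------------
# nearest-distance queries ("distance test function")
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (paired, vectorised).

    ``p``: (N, 3); ``tri``: (N, 3, 3). Standard region-classification
    algorithm on barycentric coordinates.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex A region
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    # vertex B region
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    # edge AB region
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[m] = a[m] + v_ab[m, None] * ab[m]
    done |= m

    # vertex C region
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AC region
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[m] = a[m] + w_ac[m, None] * ac[m]
    done |= m

    # edge BC region
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out[m] = b[m] + w_bc[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    if np.any(m):
        denom = va[m] + vb[m] + vc[m]
        v = vb[m] / denom
        w = vc[m] / denom
        out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


def _split_large_triangles(tri: np.ndarray, max_radius: float) -> np.ndarray:
    """Longest-edge bisection until every triangle circumradius <= max_radius.

    The union of the pieces is the original surface, so distances to the
    split triangle soup equal distances to the input mesh exactly.
    """
    for _ in range(64):  # hard stop; each pass halves the largest extent
        centroids = tri.mean(axis=1)
        radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
        big = radius > max_radius
        if not big.any():
            return tri
        t = tri[big]
        edges = np.stack(
            [
                np.linalg.norm(t[:, 1] - t[:, 2], axis=1),
                np.linalg.norm(t[:, 2] - t[:, 0], axis=1),
                np.linalg.norm(t[:, 0] - t[:, 1], axis=1),
            ],
            axis=1,
        )
        longest = np.argmax(edges, axis=1)  # edge opposite vertex `longest`
        rows = np.arange(len(t))
        a = t[rows, longest]
        b = t[rows, (longest + 1) % 3]
        c = t[rows, (longest + 2) % 3]
        mid = 0.5 * (b + c)
        halves = np.concatenate(
            [np.stack([a, b, mid], axis=1), np.stack([a, mid, c], axis=1)]
        )
        tri = np.concatenate([tri[~big], halves])
    return tri


class _MeshDistanceQuery:
    """Exact nearest point on a mesh via KD-tree candidate pruning.

    Candidate triangles are gathered by centroid proximity; a circumradius
    bound guarantees no nearer triangle is missed before the search
    terminates, so results equal the exhaustive minimum. Oversized triangles
    (e.g. cap fans) are bisected up front to keep that bound tight.
    """

    def __init__(self, mesh: TriMesh):
        if len(mesh.faces) == 0:
            raise GeometryError("mesh has no faces")
        tri = mesh.triangles
        centroids = tri.mean(axis=1)
        radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
        cap = max(2.0 * float(np.median(radius)), 1e-6)
        if radius.max() > cap:
            tri = _split_large_triangles(tri, cap)
        self.tri = tri
        self.centroids = tri.mean(axis=1)
        self.tri_radius = np.linalg.norm(
            tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.tri_radius.max())
        self.ctree = cKDTree(self.centroids)
        self.vtree = cKDTree(mesh.vertices)

    def query(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        n = len(pts)
        ntri = len(self.tri)
        best_d = np.full(n, np.inf)
        best_p = np.zeros((n, 3))
        active = np.arange(n)
        k = min(24, ntri)
        while len(active):
            d_c, idx = self.ctree.query(pts[active], k=k)
            if k == 1:
                d_c = d_c[:, None]
                idx = idx[:, None]
            cand = idx.ravel()
            qrep = np.repeat(active, k)
            cp = _closest_point_on_triangles(pts[qrep], self.tri[cand])
            d = np.linalg.norm(pts[qrep] - cp, axis=1).reshape(len(active), k)
            cp = cp.reshape(len(active), k, 3)
            j = np.argmin(d, axis=1)
            rows = np.arange(len(active))
            dmin = d[rows, j]
            upd = dmin < best_d[active]
            best_d[active[upd]] = dmin[upd]
            best_p[active[upd]] = cp[rows[upd], j[upd]]
            if k >= ntri:
                break
            # a triangle beyond the k-th centroid is at surface distance
            # >= d_c[:, -1] - rmax; finished once that cannot beat the best
            unfinished = best_d[active] > d_c[:, -1] - self.rmax
            active = active[unfinished]
            k = min(k * 4, ntri)
        return best_d, best_p


def build_distance_query(target):
    """Reusable nearest-point structure for repeated queries (e.g. ICP)."""
    if isinstance(target, TriMesh):
        return _MeshDistanceQuery(target)
    if isinstance(target, PointCloud):
        if len(target) == 0:
            raise GeometryError("empty target cloud")
        return _CloudDistanceQuery(target)
    raise GeometryError(f"unsupported target type: {type(target)!r}")


class _CloudDistanceQuery:
    def __init__(self, cloud: PointCloud):
        self.points = cloud.points
        self.tree = cKDTree(cloud.points)

    def query(self, pts):
        d, idx = self.tree.query(pts)
        return d, self.points[idx]


def nearest_points(query, target):
    """Nearest target point for each query point.

    Returns ``(distances, points)``; target may be a PointCloud, TriMesh, or
    a prebuilt structure from :func:`build_distance_query`.
    """
    if isinstance(query, PointCloud):
        pts = query.points
    else:
        pts = _as_points(query, "query")
    if len(pts) == 0:
        raise GeometryError("empty query")
    if isinstance(target, (_MeshDistanceQuery, _CloudDistanceQuery)):
        return target.query(pts)
    return build_distance_query(target).query(pts)


def nearest_distances(query, target) -> np.ndarray:
    """Per-point Euclidean distance from query to the nearest point of target.

    The "distance test function" of the registration stage: point-to-point
    for a cloud target, exact point-to-surface for a mesh target.
    """
    d, _ = nearest_points(query, target)
    return d
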