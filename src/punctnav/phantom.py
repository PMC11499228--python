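"""Synthetic phantoms standing in for cadaver CT scans and the SLI camera.

Every stage of the navigation pipeline gets a generate-and-recover test
from this module: a limb-like phantom (tapered elliptical skin with raised
bandage-fixture knobs that serve as coarse-registration landmarks, and an
off-centre tubular bone), CT voxelization into the three intensity classes
the segmentation thresholds expect (air -1000 HU, soft tissue 40 HU, bone
700 HU), a pinhole structured-light scan simulator producing one-sided
visible-surface clouds with depth noise and dropout, partial cylindrical
tube clouds with planted outliers, and known-drift injection.

The structured-light decoder itself (fringe projection, phase unwrapping)
is not simulated; the generator produces the decoder's *output* — a
visible-surface point cloud with Gaussian depth noise along each ray.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    CylinderModel,
    GeometryError,
    PointCloud,
    RigidTransform,
    TriMesh,
    apply_transform,
    compose_transforms,
)

__all__ = [
    "PhantomSpec",
    "SliCameraSpec",
    "make_phantom",
    "voxelize_ct",
    "rasterize_inside",
    "simulate_sli",
    "make_tube_cloud",
    "inject_drift",
    "AIR_HU",
    "SOFT_TISSUE_HU",
    "BONE_HU",
]

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
BONE_HU = 700.0

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class PhantomSpec:
    """Limb-like phantom: tapered elliptical skin + knobs, off-centre bone.

    Skin cross-section radii are ``skin_radii`` (mm) at the proximal end,
    scaled linearly to ``taper`` times that at the distal end. ``ridge_count``
    raised knobs of height ``ridge_height`` emulate the conspicuous features
    on the polymer bandage fixtures; their apexes are the coarse-registration
    landmarks. The bone is a tube of ``bone_radius`` offset by
    ``bone_offset`` from the skin axis with a low-order surface bump.
    """

    length: float = 160.0
    skin_radii: tuple = (45.0, 38.0)
    taper: float = 0.85
    ridge_count: int = 6
    ridge_height: float = 3.0
    ridge_sigma_z: float = 6.0
    ridge_sigma_theta: float = 0.25
    bone_radius: float = 12.0
    bone_offset: tuple = (8.0, 5.0)
    bone_bump: float = 1.5
    bone_margin: float = 12.0
    seed: int = 0
    n_theta: int = 96
    n_z: int = 81

    def __post_init__(self):
        if self.length <= 0 or min(self.skin_radii) <= 0 or self.bone_radius <= 0:
            raise GeometryError("all phantom dimensions must be > 0")
        if not 0 < self.taper <= 1:
            raise GeometryError("taper must be in (0, 1]")
        if self.ridge_count < 0:
            raise GeometryError("ridge_count must be >= 0")

    # -- analytic geometry ------------------------------------------------

    def _ridge_sites(self):
        """(theta_i, z_i) knob apex parameters, deterministic per seed."""
        if self.ridge_count == 0:
            return np.zeros((0, 2))
        rng = np.random.default_rng(self.seed)
        i = np.arange(self.ridge_count)
        theta = (i * _GOLDEN_ANGLE + rng.uniform(-0.3, 0.3, self.ridge_count)) % (2 * np.pi)
        z = self.length * (0.2 + 0.6 * (i + 0.5) / self.ridge_count)
        return np.column_stack([theta, z])

    def skin_radius(self, theta, z):
        """Skin cross-section radius at azimuth theta and height z."""
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        a, b = self.skin_radii
        ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        scale = 1.0 - (1.0 - self.taper) * z / self.length
        r = ellipse * scale
        for theta_i, z_i in self._ridge_sites():
            dth = np.angle(np.exp(1j * (theta - theta_i)))  # wrapped difference
            r = r + self.ridge_height * np.exp(
                -((z - z_i) / self.ridge_sigma_z) ** 2
                - (dth / self.ridge_sigma_theta) ** 2
            )
        return r

    def bone_radius_at(self, theta, z):
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        z0, z1 = self.bone_margin, self.length - self.bone_margin
        axial = np.sin(np.pi * (z - z0) / max(z1 - z0, 1e-9))
        return self.bone_radius + self.bone_bump * np.sin(3.0 * theta) * axial

    def skin_contains(self, points) -> np.ndarray:
        """Analytic interior test for the skin (independent of any mesh)."""
        p = np.asarray(points, dtype=float)
        z_ok = (p[:, 2] >= 0.0) & (p[:, 2] <= self.length)
        theta = np.arctan2(p[:, 1], p[:, 0])
        rr = np.hypot(p[:, 0], p[:, 1])
        return z_ok & (rr <= self.skin_radius(theta, np.clip(p[:, 2], 0, self.length)))

    def bone_contains(self, points) -> np.ndarray:
        """Analytic interior test for the bone."""
        p = np.asarray(points, dtype=float)
        ox, oy = self.bone_offset
        z0, z1 = self.bone_margin, self.length - self.bone_margin
        z_ok = (p[:, 2] >= z0) & (p[:, 2] <= z1)
        dx = p[:, 0] - ox
        dy = p[:, 1] - oy
        theta = np.arctan2(dy, dx)
        rr = np.hypot(dx, dy)
        return z_ok & (rr <= self.bone_radius_at(theta, np.clip(p[:, 2], z0, z1)))


def _tube_mesh(radius_fn, center_xy, z0, z1, n_theta, n_z) -> TriMesh:
    """Closed surface of revolution: side wall + fan caps."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(z0, z1, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    r = radius_fn(tt, zz)
    x = center_xy[0] + r * np.cos(tt)
    y = center_xy[1] + r * np.sin(tt)
    verts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])

    def vid(i, j):
        return (i % n_theta) * n_z + j

    faces = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a, b_, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b_, c])
            faces.append([a, c, d])
    bottom = len(verts)
    top = bottom + 1
    verts = np.vstack([verts, [center_xy[0], center_xy[1], z0], [center_xy[0], center_xy[1], z1]])
    for i in range(n_theta):
        faces.append([vid(i + 1, 0), vid(i, 0), bottom])
        faces.append([vid(i, n_z - 1), vid(i + 1, n_z - 1), top])
    return TriMesh(verts, np.asarray(faces))


def make_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build the phantom: ``(skin_mesh, bone_mesh, landmarks)``.

    Landmarks are the knob apex coordinates (one per ridge), usable as
    coarse-registration features. Raises if the bone does not keep a
    clearance of at least 2 mm inside the skin.
    """
    skin = _tube_mesh(
        spec.skin_radius, (0.0, 0.0), 0.0, spec.length, spec.n_theta, spec.n_z
    )
    z0, z1 = spec.bone_margin, spec.length - spec.bone_margin
    bone = _tube_mesh(
        spec.bone_radius_at,
        spec.bone_offset,
        z0,
        z1,
        max(24, spec.n_theta // 2),
        max(17, spec.n_z // 2),
    )

    # radial clearance check on a dense parameter grid
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    z = np.linspace(z0, z1, 64)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    rb = spec.bone_radius_at(tt, zz)
    bx = spec.bone_offset[0] + rb * np.cos(tt)
    by = spec.bone_offset[1] + rb * np.sin(tt)
    phi = np.arctan2(by, bx)
    clearance = spec.skin_radius(phi, zz) - np.hypot(bx, by)
    if clearance.min() <= 2.0:
        raise GeometryError(
            f"bone violates the 2 mm skin clearance (min {clearance.min():.2f} mm)"
        )

    sites = spec._ridge_sites()
    lm_r = spec.skin_radius(sites[:, 0], sites[:, 1])
    landmarks = np.column_stack(
        [lm_r * np.cos(sites[:, 0]), lm_r * np.sin(sites[:, 0]), sites[:, 1]]
    )
    return skin, bone, landmarks


# ---------------------------------------------------------------------------
# CT voxelization
# ---------------------------------------------------------------------------


def rasterize_inside(mesh: TriMesh, origin, spacing, shape) -> np.ndarray:
    """Even-odd interior rasterization of a closed mesh on a voxel grid.

    Casts one +z ray per (x, y) voxel column and toggles parity at every
    triangle crossing (2D point-in-triangle in the xy projection). Column
    sample positions carry a sub-micrometre deterministic offset so rays do
    not pass exactly through mesh vertices or edges.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    nx, ny, nz = shape
    jitter = 2.5e-4 * spacing[:2] * np.array([1.0, np.sqrt(2) - 1.0])
    xs = origin[0] + np.arange(nx) * spacing[0] + jitter[0]
    ys = origin[1] + np.arange(ny) * spacing[1] + jitter[1]
    z0 = origin[2]

    tri = mesh.triangles
    cols_all = []
    ks_all = []
    for t in tri:
        p0, p1, p2 = t
        denom = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
        if abs(denom) < 1e-12:
            continue  # triangle vertical in xy: ray parallel, no crossing
        i0 = max(0, int(np.ceil((min(p0[0], p1[0], p2[0]) - xs[0]) / spacing[0])))
        i1 = min(nx - 1, int(np.floor((max(p0[0], p1[0], p2[0]) - xs[0]) / spacing[0])))
        j0 = max(0, int(np.ceil((min(p0[1], p1[1], p2[1]) - ys[0]) / spacing[1])))
        j1 = min(ny - 1, int(np.floor((max(p0[1], p1[1], p2[1]) - ys[0]) / spacing[1])))
        if i1 < i0 or j1 < j0:
            continue
        gx = xs[i0 : i1 + 1][:, None]
        gy = ys[j0 : j1 + 1][None, :]
        l1 = ((gx - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (gy - p0[1])) / denom
        l2 = ((p1[0] - p0[0]) * (gy - p0[1]) - (gx - p0[0]) * (p1[1] - p0[1])) / denom
        inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
        if not inside.any():
            continue
        zc = p0[2] + l1 * (p1[2] - p0[2]) + l2 * (p2[2] - p0[2])
        ii, jj = np.nonzero(inside)
        cols_all.append((ii + i0) * ny + (jj + j0))
        # crossing at height zc toggles parity for voxel centers >= zc
        ks_all.append(np.ceil((zc[inside] - z0) / spacing[2]).astype(np.int64))

    grid = np.zeros((nx * ny, nz + 1), dtype=np.int16)
    if cols_all:
        cols = np.concatenate(cols_all)
        ks = np.clip(np.concatenate(ks_all), 0, nz)
        np.add.at(grid, (cols, ks), 1)
    parity = np.cumsum(grid, axis=1)[:, :nz] % 2
    return parity.astype(bool).reshape(nx, ny, nz)


def voxelize_ct(skin: TriMesh, bone: TriMesh, spacing: float = 1.0, pad: float = 5.0):
    """CT-like volume from the phantom meshes.

    Air (-1000 HU) outside the skin, soft tissue (40 HU) inside the skin,
    bone (700 HU) inside the bone. Both meshes must be closed.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be > 0")
    for name, mesh in (("skin", skin), ("bone", bone)):
        if not mesh.to_trimesh().is_watertight:
            raise GeometryError(f"{name} mesh is not closed; cannot voxelize")
    from .geometry import Volume

    lo = skin.vertices.min(axis=0) - pad
    hi = skin.vertices.max(axis=0) + pad
    sp = np.full(3, float(spacing))
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp[i])) + 1 for i in range(3))
    in_skin = rasterize_inside(skin, lo, sp, shape)
    in_bone = rasterize_inside(bone, lo, sp, shape)
    values = np.full(shape, AIR_HU, dtype=np.float32)
    values[in_skin] = SOFT_TISSUE_HU
    values[in_bone] = BONE_HU
    return Volume(values, sp, lo)


# ---------------------------------------------------------------------------
# structured-light scan simulation
# ---------------------------------------------------------------------------


@dataclass
class SliCameraSpec:
    """Pinhole camera for visible-surface sampling.

    Defaults mimic a structured-light head mounted ~1.2 m above the scene
    (working distance 0.9-1.5 m, field of view ~0.8 m at full range) with
    0.1 mm depth noise.
    """

    position: np.ndarray = field(default_factory=lambda: np.array([0.0, -1200.0, 80.0]))
    look_at: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 80.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    width: int = 128
    height: int = 96
    fov_deg: float = 30.0
    noise_sigma: float = 0.1
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).ravel()
        self.look_at = np.asarray(self.look_at, dtype=float).ravel()
        self.up = np.asarray(self.up, dtype=float).ravel()
        if self.width < 16 or self.height < 16:
            raise GeometryError("camera grid must be at least 16x16")
        if self.noise_sigma < 0:
            raise GeometryError("noise sigma must be >= 0")
        if not 0 <= self.dropout < 1:
            raise GeometryError("dropout must be in [0, 1)")

    def frame(self):
        """Orthonormal camera frame ``(forward, right, up)``."""
        fwd = self.look_at - self.position
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, self.up)
        nr = np.linalg.norm(right)
        if nr < 1e-9:
            raise GeometryError("up vector is parallel to the viewing direction")
        right /= nr
        return fwd, right, np.cross(right, fwd)

    def ray_directions(self) -> np.ndarray:
        fwd, right, upv = self.frame()
        tan_h = np.tan(np.deg2rad(self.fov_deg) / 2.0)
        tan_v = tan_h * self.height / self.width
        sx = (np.arange(self.width) + 0.5) / self.width * 2.0 - 1.0
        sy = (np.arange(self.height) + 0.5) / self.height * 2.0 - 1.0
        gx, gy = np.meshgrid(sx, sy, indexing="ij")
        dirs = (
            fwd[None, :]
            + (gx.ravel() * tan_h)[:, None] * right[None, :]
            + (gy.ravel() * tan_v)[:, None] * upv[None, :]
        )
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _ray_mesh_first_hit(cam: SliCameraSpec, dirs, mesh: TriMesh):
    """First-intersection distances for the camera's pixel rays.

    Candidate ray/triangle pairs come from rasterising each (back-face
    culled) triangle's projected bounding box into the pixel grid — the
    perspective projection of a triangle is a triangle, so any pixel-centre
    ray hitting it lies inside that box. Exact Möller-Trumbore on the pairs.
    Returns ray parameters t (np.inf for misses), indexed like
    ``ray_directions()``.
    """
    origin = cam.position
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    normals = np.cross(e1, e2)
    # for a closed mesh the first hit is always front facing
    facing = np.einsum("ij,ij->i", v0 - origin, normals) < 0
    if np.any(facing):
        tri = tri[facing]
        v0, e1, e2 = v0[facing], e1[facing], e2[facing]

    fwd, right, upv = cam.frame()
    tan_h = np.tan(np.deg2rad(cam.fov_deg) / 2.0)
    tan_v = tan_h * cam.height / cam.width
    rel = tri - origin  # (T, 3, 3)
    z = rel @ fwd
    w, h = cam.width, cam.height
    tmin = np.full(w * h, np.inf)
    ok_z = np.all(z > 1e-9, axis=1)  # skip triangles touching the camera plane
    if not np.any(ok_z):
        return tmin
    rel, z = rel[ok_z], z[ok_z]
    v0, e1, e2 = v0[ok_z], e1[ok_z], e2[ok_z]
    # projected pixel coordinates of the vertices
    px = ((rel @ right) / (z * tan_h) + 1.0) * 0.5 * w - 0.5
    py = ((rel @ upv) / (z * tan_v) + 1.0) * 0.5 * h - 0.5
    i0 = np.clip(np.ceil(px.min(axis=1)), 0, w - 1).astype(np.int64)
    i1 = np.clip(np.floor(px.max(axis=1)), 0, w - 1).astype(np.int64)
    j0 = np.clip(np.ceil(py.min(axis=1)), 0, h - 1).astype(np.int64)
    j1 = np.clip(np.floor(py.max(axis=1)), 0, h - 1).astype(np.int64)
    # drop boxes that fell entirely outside the image
    valid = (np.floor(px.max(axis=1)) >= 0) & (np.ceil(px.min(axis=1)) <= w - 1) \
        & (np.floor(py.max(axis=1)) >= 0) & (np.ceil(py.min(axis=1)) <= h - 1) \
        & (i1 >= i0) & (j1 >= j0)
    if not np.any(valid):
        return tmin
    i0, i1, j0, j1 = i0[valid], i1[valid], j0[valid], j1[valid]
    v0, e1, e2 = v0[valid], e1[valid], e2[valid]

    ncols = j1 - j0 + 1
    counts = (i1 - i0 + 1) * ncols
    total = int(counts.sum())
    trep = np.repeat(np.arange(len(counts)), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    k = np.arange(total) - starts[trep]
    pix_i = i0[trep] + k // ncols[trep]
    pix_j = j0[trep] + k % ncols[trep]
    pix = pix_i * h + pix_j

    dirs_p = dirs[pix]
    a, b, c = v0[trep], e1[trep], e2[trep]
    pvec = np.cross(dirs_p, c)
    det = np.einsum("ij,ij->i", b, pvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        tvec = origin[None, :] - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, b)
        v = np.einsum("ij,ij->i", dirs_p, qvec) * inv
        t = np.einsum("ij,ij->i", c, qvec) * inv
    ok = (
        (np.abs(det) > 1e-12)
        & (u >= -1e-12)
        & (v >= -1e-12)
        & (u + v <= 1 + 1e-12)
        & (t > 1e-6)
    )
    np.minimum.at(tmin, pix[ok], t[ok])
    return tmin


def simulate_sli(mesh: TriMesh, cam: SliCameraSpec = SliCameraSpec()) -> PointCloud:
    """Visible-surface point cloud of a mesh as the SLI camera would see it.

    One ray per grid cell through the pinhole; only the first intersection
    is kept (hidden surfaces absent); each point is perturbed along its ray
    by Gaussian depth noise; a ``dropout`` fraction of points is removed at
    random. Deterministic per seed.
    """
    if len(mesh.faces) == 0:
        raise GeometryError("mesh has no faces")
    dirs = cam.ray_directions()
    t = _ray_mesh_first_hit(cam, dirs, mesh)
    hit = np.isfinite(t)
    if not hit.any():
        raise GeometryError("no camera ray hits the mesh")
    rng = np.random.default_rng(cam.seed)
    t_hit = t[hit]
    d_hit = dirs[hit]
    if cam.noise_sigma > 0:
        t_hit = t_hit + rng.normal(0.0, cam.noise_sigma, len(t_hit))
    pts = cam.position + t_hit[:, None] * d_hit
    if cam.dropout > 0:
        n = len(pts)
        n_drop = int(np.floor(cam.dropout * n + 0.5))
        drop = rng.choice(n, size=n_drop, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        pts = pts[keep]
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# guiding-tube clouds and drift injection
# ---------------------------------------------------------------------------


def make_tube_cloud(
    tube: CylinderModel,
    angular_coverage: float = 180.0,
    n: int = 2000,
    noise_sigma: float = 0.1,
    outlier_fraction: float = 0.0,
    seed: int = 0,
):
    """Partial-view cylinder scan: ``(PointCloud, true_inlier_flags)``.

    ``n`` total points; ``round(outlier_fraction * n)`` of them are outliers
    uniform in the bounding box of the scanned tube points, the rest lie on
    the visible angular sector (centred on a fixed reference direction
    perpendicular to the axis) with radial Gaussian noise.
    """
    if n < 10:
        raise GeometryError("need at least 10 points")
    if not 0 < angular_coverage <= 360:
        raise GeometryError("angular_coverage must be in (0, 360]")
    if not 0 <= outlier_fraction < 1:
        raise GeometryError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    w = tube.axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)

    n_out = int(np.floor(outlier_fraction * n + 0.5))
    n_in = n - n_out
    half = np.deg2rad(angular_coverage) / 2.0
    theta = rng.uniform(-half, half, n_in)
    tpar = rng.uniform(-tube.length / 2.0, tube.length / 2.0, n_in)
    r = np.full(n_in, tube.radius)
    if noise_sigma > 0:
        r += rng.normal(0.0, noise_sigma, n_in)
    radial = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    inl = tube.center + tpar[:, None] * w + r[:, None] * radial

    lo = inl.min(axis=0)
    hi = inl.max(axis=0)
    out = rng.uniform(lo, hi, size=(n_out, 3))

    pts = np.vstack([inl, out])
    flags = np.zeros(n, dtype=bool)
    flags[:n_in] = True
    perm = rng.permutation(n)
    return PointCloud(pts[perm]), flags[perm]


def inject_drift(
    skin: TriMesh,
    bone: TriMesh,
    surface_shift: RigidTransform,
    extra_bone_shift: RigidTransform,
):
    """Move the phantom as a post-operative scan would see it.

    The skin moves by ``surface_shift``; the bone additionally by
    ``extra_bone_shift`` (applied after the surface motion), emulating bone
    displacement relative to the immobilised surface. Returns
    ``(shifted_skin, shifted_bone, truth)`` where ``truth`` records the
    applied transforms and the magnitude of the extra bone translation.
    """
    bone_total = compose_transforms(surface_shift, extra_bone_shift)
    truth = {
        "surface_shift": {
            "rotation": surface_shift.rotation.tolist(),
            "translation": surface_shift.translation.tolist(),
        },
        "extra_bone_shift": {
            "rotation": extra_bone_shift.rotation.tolist(),
            "translation": extra_bone_shift.translation.tolist(),
        },
        "bone_total": {
            "rotation": bone_total.rotation.tolist(),
            "translation": bone_total.translation.tolist(),
        },
        "extra_bone_translation_mm": float(np.linalg.norm(extra_bone_shift.translation)),
    }
    return apply_transform(skin, surface_shift), apply_transform(bone, bone_total), truth
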