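import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from punctnav.geometry import PointCloud, RigidTransform, TriMesh, rotation_about_axis
from punctnav.phantom import PhantomSpec, SliCameraSpec, make_phantom, simulate_sli

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rigid(rng: np.random.Generator, max_angle_deg=180.0, max_shift=20.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    shift = rng.uniform(-max_shift, max_shift, 3)
    return RigidTransform(rotation_about_axis(axis, angle), shift)


def sample_mesh_points(mesh: TriMesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish surface samples: area-weighted triangles, barycentric points."""
    tri = mesh.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    idx = rng.choice(len(tri), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.uniform(size=n))
    r2 = rng.uniform(size=n)
    a, b, c = tri[idx, 0], tri[idx, 1], tri[idx, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def grid_plane_mesh(extent=50.0, n=21, z=0.0) -> TriMesh:
    """Flat triangulated square in the z-plane (locally planar drift oracle)."""
    x, y = np.meshgrid(np.linspace(0, extent, n), np.linspace(0, extent, n), indexing="ij")
    verts = np.column_stack([x.ravel(), y.ravel(), np.full(x.size, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            c = (i + 1) * n + j + 1
            d = i * n + j + 1
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def phantom():
    """Default limb phantom: (spec, skin mesh, bone mesh, landmarks)."""
    spec = PhantomSpec()
    skin, bone, lms = make_phantom(spec)
    return spec, skin, bone, lms


@pytest.fixture(scope="session")
def phantom_scan(phantom):
    """Noiseless dense structured-light scan of the phantom skin."""
    _, skin, _, _ = phantom
    cam = SliCameraSpec(noise_sigma=0.0, fov_deg=12.0, width=160, height=120, seed=0)
    return simulate_sli(skin, cam)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_cloud(rng):
    return PointCloud(rng.normal(0.0, 10.0, (50, 3)))
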