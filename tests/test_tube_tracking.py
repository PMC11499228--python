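"""Normal estimation, RANSAC cylinder fitting, and path-deviation scoring."""

import numpy as np
import pytest

from punctnav.geometry import CylinderModel, GeometryError, PointCloud, PuncturePath, apply_transform
from punctnav.phantom import make_tube_cloud
from punctnav.tube_tracking import (
    CylinderFitError,
    RansacParams,
    check_tolerance,
    cylinder_mesh,
    estimate_normals,
    fit_cylinder_ransac,
    path_deviation,
)

from conftest import random_rigid

_AXIS = np.array([0.2, 0.1, 1.0]) / np.linalg.norm([0.2, 0.1, 1.0])
_TUBE = CylinderModel(center=[10.0, 5.0, 40.0], axis=_AXIS, radius=5.0, length=80.0)


def _axis_angle_deg(a, b) -> float:
    return float(np.degrees(np.arccos(min(1.0, abs(float(np.dot(a, b)))))))


class TestEstimateNormals:
    def test_plane_normals_point_along_z(self, rng):
        pts = np.column_stack([rng.uniform(0, 50, 300), rng.uniform(0, 50, 300), np.zeros(300)])
        out = estimate_normals(PointCloud(pts), k=8, viewpoint=[25.0, 25.0, 100.0])
        np.testing.assert_allclose(np.abs(out.normals[:, 2]), 1.0, atol=1e-6)
        assert np.all(out.normals[:, 2] > 0)  # oriented toward the viewpoint

    def test_cylinder_normals_perpendicular_to_axis(self):
        fat = CylinderModel(center=_TUBE.center, axis=_TUBE.axis, radius=10.0, length=80.0)
        cloud, _ = make_tube_cloud(fat, angular_coverage=360, n=6000, noise_sigma=0.0, seed=0)
        out = estimate_normals(cloud, k=12)
        dot = np.abs(out.normals @ fat.axis)
        angles = np.degrees(np.arcsin(np.clip(dot, 0, 1)))
        assert np.percentile(angles, 95) < 2.0  # tilt from the radial direction

    def test_k_larger_than_cloud_rejected(self, rng):
        cloud = PointCloud(rng.normal(0, 1, (10, 3)))
        with pytest.raises(GeometryError):
            estimate_normals(cloud, k=10)

    def test_k_below_three_rejected(self, small_cloud):
        with pytest.raises(GeometryError):
            estimate_normals(small_cloud, k=2)


class TestFitCylinderRansac:
    def test_exact_cloud_recovers_all_parameters(self):
        cloud, _ = make_tube_cloud(_TUBE, angular_coverage=360, n=2000, noise_sigma=0.0, seed=0)
        model, inliers = fit_cylinder_ransac(cloud, RansacParams(seed=0, max_iterations=500))
        assert abs(model.radius - _TUBE.radius) < 1e-6
        assert _axis_angle_deg(model.axis, _TUBE.axis) < 0.01
        assert abs(model.length - _TUBE.length) < 0.5
        assert inliers.all()

    def test_noisy_outlier_cloud_recovered(self):
        r_err, a_err, flag_acc = [], [], []
        for seed in range(5):
            cloud, flags = make_tube_cloud(
                _TUBE, angular_coverage=180, n=2000, noise_sigma=0.2,
                outlier_fraction=0.25, seed=seed,
            )
            model, inliers = fit_cylinder_ransac(
                cloud, RansacParams(distance_threshold=0.6, max_iterations=1000, seed=seed)
            )
            r_err.append(abs(model.radius - _TUBE.radius))
            a_err.append(_axis_angle_deg(model.axis, _TUBE.axis))
            flag_acc.append((inliers == flags).mean())
        assert np.median(r_err) < 0.1
        assert np.median(a_err) < 1.0
        assert np.median(flag_acc) >= 0.95

    def test_all_outlier_cloud_raises_fit_failure(self, rng):
        cloud = PointCloud(rng.uniform(-50, 50, (500, 3)))
        with pytest.raises(CylinderFitError):
            fit_cylinder_ransac(cloud, RansacParams(min_inlier_fraction=0.5, seed=0,
                                                    max_iterations=200))

    def test_inlier_flags_reproducible_from_returned_model(self):
        cloud, _ = make_tube_cloud(
            _TUBE, angular_coverage=180, n=1500, noise_sigma=0.2, outlier_fraction=0.2, seed=5
        )
        p = RansacParams(distance_threshold=0.6, max_iterations=600, seed=5)
        model, inliers = fit_cylinder_ransac(cloud, p)
        rel = cloud.points - model.center
        d_axis = np.linalg.norm(np.cross(rel, model.axis), axis=1)
        rescored = np.abs(d_axis - model.radius) <= p.distance_threshold
        np.testing.assert_array_equal(rescored, inliers)

    def test_fit_equivariant_under_rigid_motion(self, rng):
        cloud, _ = make_tube_cloud(_TUBE, angular_coverage=200, n=1500, noise_sigma=0.0, seed=2)
        p = RansacParams(seed=2, max_iterations=400)
        base, _ = fit_cylinder_ransac(cloud, p)
        g = random_rigid(rng, max_angle_deg=40, max_shift=30)
        moved, _ = fit_cylinder_ransac(apply_transform(cloud, g), p)
        assert abs(moved.radius - base.radius) < 1e-6
        assert abs(moved.length - base.length) < 1e-6
        assert _axis_angle_deg(moved.axis, g.rotation @ base.axis) < 1e-4
        # centers agree up to sliding along the (sign-ambiguous) axis
        np.testing.assert_allclose(
            np.cross(moved.center - g.apply(base.center), moved.axis), 0.0, atol=1e-5
        )

    def test_radius_error_grows_with_noise(self):
        medians = []
        for sigma in (0.0, 0.1, 0.3):
            errs = []
            for seed in range(5):
                cloud, _ = make_tube_cloud(
                    _TUBE, angular_coverage=180, n=1500, noise_sigma=sigma, seed=seed
                )
                model, _ = fit_cylinder_ransac(
                    cloud, RansacParams(distance_threshold=0.6, max_iterations=500, seed=seed)
                )
                errs.append(abs(model.radius - _TUBE.radius))
            medians.append(np.median(errs))
        assert medians == sorted(medians)


class TestPathDeviation:
    def test_tube_on_path_has_zero_deviation(self):
        path = PuncturePath(entry=_TUBE.center - 40.0 * _AXIS, direction=_AXIS, depth=30.0)
        dev = path_deviation(_TUBE, path)
        assert dev.angle < 1e-5
        assert dev.lateral_offset < 1e-9
        assert dev.tip_gap < 1e-9  # proximal tube end sits on the entry point

    def test_tilt_about_entry_point_gives_pure_angle(self):
        from punctnav.geometry import rotation_about_axis

        entry = _TUBE.center - 40.0 * _AXIS
        path = PuncturePath(entry=entry, direction=_AXIS, depth=30.0)
        rot = rotation_about_axis(np.cross(_AXIS, [1.0, 0, 0]), 10.0)
        tilted = CylinderModel(
            center=entry + rot @ (_TUBE.center - entry),
            axis=rot @ _AXIS, radius=_TUBE.radius, length=_TUBE.length,
        )
        dev = path_deviation(tilted, path)
        assert abs(dev.angle - 10.0) < 1e-6
        assert dev.lateral_offset < 1e-9

    def test_perpendicular_shift_gives_pure_offset(self):
        path = PuncturePath(entry=_TUBE.center - 40.0 * _AXIS, direction=_AXIS, depth=30.0)
        perp = np.cross(_AXIS, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        shifted = CylinderModel(center=_TUBE.center + 3.0 * perp, axis=_AXIS,
                                radius=_TUBE.radius, length=_TUBE.length)
        dev = path_deviation(shifted, path)
        assert abs(dev.lateral_offset - 3.0) < 1e-9
        assert dev.angle < 1e-5

    def test_symmetric_under_axis_flip(self):
        path = PuncturePath(entry=[0.0, 1.0, 2.0], direction=[0.0, 0.0, 1.0], depth=25.0)
        flipped = CylinderModel(center=_TUBE.center, axis=-_TUBE.axis,
                                radius=_TUBE.radius, length=_TUBE.length)
        d1 = path_deviation(_TUBE, path)
        d2 = path_deviation(flipped, path)
        assert abs(d1.angle - d2.angle) < 1e-12
        assert abs(d1.lateral_offset - d2.lateral_offset) < 1e-12
        assert abs(d1.tip_gap - d2.tip_gap) < 1e-12


class TestCheckTolerance:
    def test_perfect_alignment_passes(self):
        from punctnav.tube_tracking import PathDeviation

        ok, msg = check_tolerance(PathDeviation(0.0, 0.0, 0.0), 3.0, 2.0)
        assert ok

    def test_angle_violation_named_in_message(self):
        from punctnav.tube_tracking import PathDeviation

        ok, msg = check_tolerance(PathDeviation(5.0, 0.5, 0.0), max_angle=3.0, max_offset=2.0)
        assert not ok
        assert "angle" in msg and "offset" not in msg

    def test_boundary_is_inclusive(self):
        from punctnav.tube_tracking import PathDeviation

        ok, _ = check_tolerance(PathDeviation(3.0, 2.0, 0.0), max_angle=3.0, max_offset=2.0)
        assert ok


def test_cylinder_mesh_matches_model_dimensions():
    mesh = cylinder_mesh(_TUBE, sections=64)
    tm = mesh.to_trimesh()
    assert tm.is_watertight
    # extent along the tube axis equals the length; radial extent ~ radius
    proj = (mesh.vertices - _TUBE.center) @ _TUBE.axis
    assert abs((proj.max() - proj.min()) - _TUBE.length) < 1e-6
    rad = np.linalg.norm(np.cross(mesh.vertices - _TUBE.center, _TUBE.axis), axis=1)
    assert abs(rad.max() - _TUBE.radius) < 0.05
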