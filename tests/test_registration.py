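"""Landmark alignment, trimmed ICP refinement, and the two-step driver."""

import numpy as np
import pytest

from punctnav.geometry import (
    PointCloud,
    RigidTransform,
    apply_transform,
    compose_transforms,
    rotation_about_axis,
)
from punctnav.phantom import SliCameraSpec, simulate_sli
from punctnav.registration import (
    DegenerateLandmarkError,
    IcpParams,
    coarse_align,
    crop_and_denoise,
    icp_refine,
    register_two_step,
)

from conftest import random_rigid, sample_mesh_points


def _pose_rms(t_est: RigidTransform, t_true: RigidTransform, pts: np.ndarray) -> float:
    """Point-RMS discrepancy of two transforms over a point set."""
    d = np.linalg.norm(t_est.apply(pts) - t_true.apply(pts), axis=1)
    return float(np.sqrt((d**2).mean()))


_FAST_ICP = dict(subsample_size=2000, max_iterations=60)


class TestCoarseAlign:
    def test_identical_landmarks_give_identity(self, rng):
        lms = rng.normal(0, 40, (5, 3))
        t = coarse_align(lms, lms)
        np.testing.assert_allclose(t.matrix(), np.eye(4), atol=1e-9)

    def test_known_transform_recovered(self, rng):
        lms = rng.normal(0, 40, (5, 3))
        g = random_rigid(rng)
        t = coarse_align(lms, g.apply(lms))
        np.testing.assert_allclose(t.matrix(), g.matrix(), atol=1e-9)

    def test_noise_residual_bounded_by_three_sigma(self):
        sigma = 0.1
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lms = rng.normal(0, 40, (4, 3))
            g = random_rigid(rng, max_angle_deg=30, max_shift=10)
            noisy = g.apply(lms) + rng.normal(0, sigma, lms.shape)
            t = coarse_align(lms, noisy)
            res = np.linalg.norm(t.apply(lms) - noisy, axis=1)
            worst = max(worst, np.sqrt((res**2).mean()))
        assert worst <= 3 * sigma

    def test_collinear_landmarks_rejected(self):
        lms = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateLandmarkError):
            coarse_align(lms, lms + 1.0)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(DegenerateLandmarkError):
            coarse_align(np.zeros((2, 3)), np.zeros((2, 3)))


class TestIcpRefine:
    def test_self_alignment_converges_immediately(self, phantom, phantom_scan):
        _, skin, _, _ = phantom
        res = icp_refine(
            phantom_scan, skin, RigidTransform.identity(),
            IcpParams(seed=0, **_FAST_ICP),
        )
        assert res.converged
        assert res.iterations <= 2
        assert res.rms < 1e-6

    def test_small_pose_recovered_on_noiseless_data(self, phantom, rng):
        # full-surface samples: caps and fixture knobs pin all six DOF, so
        # fine refinement alone must undo a small pose without any trimming
        _, skin, _, _ = phantom
        samples = sample_mesh_points(skin, 3000, rng)
        g = RigidTransform(
            rotation_about_axis([0.2, 1.0, 0.1], 4.0), np.array([3.0, -2.0, 4.0])
        )
        src = PointCloud(g.apply(samples))
        res = icp_refine(src, skin, RigidTransform.identity(),
                         IcpParams(seed=0, trim_fraction=0.0, subsample_size=2000,
                                   max_iterations=150))
        # the refinement should undo g
        err = _pose_rms(res.total, RigidTransform(g.rotation.T, -g.rotation.T @ g.translation), src.points)
        assert err < 0.05

    def test_trimming_defeats_planted_outliers(self, phantom, rng):
        _, skin, _, _ = phantom
        samples = sample_mesh_points(skin, 3000, rng)
        g = RigidTransform(rotation_about_axis([0, 0, 1], 3.0), np.array([2.0, 1.0, -2.0]))
        pts = g.apply(samples)
        n_out = int(0.2 * len(pts))
        outliers = pts[rng.choice(len(pts), n_out, replace=False)] + np.array([50.0, 0.0, 0.0])
        src = PointCloud(np.vstack([pts, outliers]))
        ginv = RigidTransform(g.rotation.T, -g.rotation.T @ g.translation)

        # trimming discards the largest-distance inliers too, so the last
        # fraction of a millimetre is approached slowly: give it iterations
        res_trim = icp_refine(src, skin, RigidTransform.identity(),
                              IcpParams(seed=0, trim_fraction=0.3, subsample_size=1200,
                                        max_iterations=600))
        err_trim = _pose_rms(res_trim.total, ginv, pts)
        res_raw = icp_refine(src, skin, RigidTransform.identity(),
                             IcpParams(seed=0, trim_fraction=0.0, subsample_size=1200,
                                       max_iterations=600))
        err_raw = _pose_rms(res_raw.total, ginv, pts)
        assert err_trim < 0.1
        assert err_raw > 0.1

    def test_rms_trace_monotone_nonincreasing(self, phantom, phantom_scan):
        _, skin, _, _ = phantom
        rng = np.random.default_rng(7)
        g = RigidTransform(rotation_about_axis([1, 0, 0], 4.0), np.array([-3.0, 2.0, 1.0]))
        src = PointCloud(g.apply(phantom_scan.points) + rng.normal(0, 0.2, phantom_scan.points.shape))
        res = icp_refine(src, skin, RigidTransform.identity(), IcpParams(seed=1, **_FAST_ICP))
        assert np.all(np.diff(res.rms_trace) <= 1e-9)

    def test_total_is_exact_composition_of_init_and_fine(self, phantom, phantom_scan):
        _, skin, _, _ = phantom
        init = RigidTransform(rotation_about_axis([0, 1, 0], 2.0), np.array([1.0, 0.0, -1.0]))
        res = icp_refine(phantom_scan, skin, init, IcpParams(seed=0, subsample_size=1000, max_iterations=10))
        expect = compose_transforms(init, res.fine)
        np.testing.assert_allclose(res.total.matrix(), expect.matrix(), atol=1e-12)


class TestRegisterTwoStep:
    def test_noiseless_scan_reaches_machine_zero(self, phantom, phantom_scan):
        _, skin, _, lms = phantom
        g = RigidTransform(rotation_about_axis([0.3, 1, 0.2], 4.0), np.array([3.0, -2.0, 4.0]))
        sli = PointCloud(g.apply(phantom_scan.points))
        res = register_two_step(sli, skin, (lms, g.apply(lms)), IcpParams(seed=0, **_FAST_ICP))
        assert res.converged
        assert res.rms < 0.05
        assert _pose_rms(res.total, g, skin.vertices) < 0.05

    def test_unequal_landmark_lists_rejected(self, phantom, phantom_scan):
        _, skin, _, lms = phantom
        with pytest.raises(DegenerateLandmarkError):
            register_two_step(phantom_scan, skin, (lms, lms[:-1]), IcpParams(seed=0))

    def test_equivariant_under_global_rigid_motion(self, phantom, phantom_scan):
        _, skin, _, lms = phantom
        rng = np.random.default_rng(11)
        g0 = RigidTransform(rotation_about_axis([0, 0, 1], 3.0), np.array([2.0, -1.0, 3.0]))
        sli = PointCloud(g0.apply(phantom_scan.points))
        params = IcpParams(seed=0, subsample_size=1500, max_iterations=40)
        base = register_two_step(sli, skin, (lms, g0.apply(lms)), params)

        g = random_rigid(rng, max_angle_deg=25, max_shift=30)
        moved = PointCloud(g.apply(sli.points))
        res = register_two_step(moved, skin, (lms, g.apply(g0.apply(lms))), params)
        expect = compose_transforms(base.total, g)
        assert _pose_rms(res.total, expect, skin.vertices) < 1e-6

    def test_recovery_error_monotone_in_scan_noise(self, phantom):
        _, skin, _, lms = phantom
        g = RigidTransform(rotation_about_axis([0.1, 1, 0], 3.0), np.array([2.0, 2.0, -3.0]))
        cam_base = dict(fov_deg=12.0, width=96, height=72)
        params = IcpParams(seed=0, subsample_size=1200, max_iterations=40)
        medians = []
        for sigma in (0.0, 0.1, 0.3, 0.5):
            errs = []
            for seed in range(5):
                cam = SliCameraSpec(noise_sigma=sigma, seed=seed, **cam_base)
                scan = simulate_sli(skin, cam)
                rng = np.random.default_rng(100 + seed)
                sli = PointCloud(g.apply(scan.points))
                lm_noise = rng.normal(0, sigma, lms.shape)
                res = register_two_step(sli, skin, (lms, g.apply(lms) + lm_noise), params)
                errs.append(_pose_rms(res.total, g, scan.points))
            medians.append(np.median(errs))
        assert medians == sorted(medians)


class TestCropAndDenoise:
    def test_clean_cloud_inside_box_unchanged(self):
        # perfectly regular ring: every point has the same neighbour distances,
        # so statistical outlier removal must keep all of them
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = PointCloud(np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros(100)]))
        out = crop_and_denoise(ring, box=([-100] * 3, [100] * 3))
        np.testing.assert_array_equal(out.points, ring.points)

    def test_isolated_far_points_removed_exactly(self, rng):
        dense = rng.normal(0, 5, (400, 3))
        # 10 mutually isolated points ~100 mm out in distinct directions
        dirs = rng.normal(size=(10, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        far = dirs * rng.uniform(90, 110, 10)[:, None]
        cloud = PointCloud(np.vstack([dense, far]))
        out = crop_and_denoise(cloud, nn_k=8, sigma_factor=2.0)
        assert len(out) == 400
        assert np.abs(out.points).max() < 50

    def test_half_space_crop_matches_brute_force_count(self, rng):
        pts = rng.normal(0, 10, (300, 3))
        centroid = pts.mean(axis=0)
        box = (np.array([centroid[0], -1e6, -1e6]), np.array([1e6, 1e6, 1e6]))
        out = crop_and_denoise(PointCloud(pts), box=box, sigma_factor=1e9)
        assert len(out) == int((pts[:, 0] >= centroid[0]).sum())

    def test_box_excluding_all_points_rejected(self, small_cloud):
        from punctnav.geometry import GeometryError

        with pytest.raises(GeometryError):
            crop_and_denoise(small_cloud, box=([1e5] * 3, [2e5] * 3))

    def test_scalars_and_normals_carried_through(self, rng):
        normals = np.tile([0.0, 0.0, 1.0], (100, 1))
        cloud = PointCloud(rng.normal(0, 5, (100, 3)), normals, np.arange(100.0))
        out = crop_and_denoise(cloud, sigma_factor=1e9)
        assert out.normals is not None and out.scalars is not None
        assert len(out.normals) == len(out.points) == len(out.scalars)
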