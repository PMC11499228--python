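"""End-to-end orchestration: simulate -> segment -> register -> track-tube
-> drift -> summarize.

``run_pipeline`` executes the full desk-scale rehearsal of the navigation
workflow on a synthetic phantom and writes one JSON artifact per stage plus
a combined report. Every random choice derives from the single configured
seed, so two runs with the same config produce identical numeric output.

``drift_rehearsal`` is the library entry point for the drift study: build a
phantom, CT-voxelize it before and after a known injected drift, register
the two CT surface models (optionally with scan noise on the registration
cloud), and measure surface and skeletal drift residual to that
registration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .ct_modeling import plan_path, segment_preset
from .drift import cohort_summary, drift_field, load_reference_table, paired_difference, skeletal_drift
from .geometry import (
    CylinderModel,
    PointCloud,
    RigidTransform,
    rotation_about_axis,
)
from .phantom import PhantomSpec, SliCameraSpec, inject_drift, make_phantom, make_tube_cloud, simulate_sli, voxelize_ct
from .registration import IcpParams, register_two_step
from .tube_tracking import RansacParams, check_tolerance, fit_cylinder_ransac, path_deviation

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "drift_rehearsal"]

log = logging.getLogger("punctnav")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of the rehearsal pipeline (YAML-serialisable).

    Only scalars and small lists, so a config file round-trips exactly.
    """

    outdir: str = "punctnav_run"
    seed: int = 0
    spacing: float = 1.0
    # intraoperative pose of the specimen in the scanner frame
    intra_rotation_deg: float = 4.0
    intra_rotation_axis: tuple = (0.3, 1.0, 0.2)
    intra_translation: tuple = (3.0, -2.0, 4.0)
    # SLI camera
    scan_fov_deg: float = 12.0
    scan_width: int = 160
    scan_height: int = 120
    scan_noise_sigma: float = 0.1
    # ICP
    icp_max_iterations: int = 100
    icp_rel_tolerance: float = 1e-6
    icp_subsample: int = 5000
    icp_trim_fraction: float = 0.2
    quality_threshold: float = 1.0
    max_restarts: int = 3
    # tube tracking
    tube_radius: float = 5.0
    tube_length: float = 80.0
    ransac_threshold: float = 0.6
    ransac_iterations: int = 1000
    tolerance_angle_deg: float = 3.0
    tolerance_offset_mm: float = 2.0
    # drift injection
    postop_rotation_deg: float = 3.0
    postop_translation: tuple = (4.0, -3.0, 2.0)
    extra_bone_translation: tuple = (0.3, 0.0, 0.0)
    # optional externally supplied inputs (override generated artifacts)
    volume: str = ""
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    def icp_params(self, seed_offset: int = 0) -> IcpParams:
        return IcpParams(
            max_iterations=self.icp_max_iterations,
            rel_tolerance=self.icp_rel_tolerance,
            subsample_size=self.icp_subsample,
            trim_fraction=self.icp_trim_fraction,
            seed=self.seed + seed_offset,
        )


def _transform_from_dict(d) -> RigidTransform:
    return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def _write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def drift_rehearsal(
    spec: PhantomSpec,
    surface_shift: RigidTransform,
    extra_bone_shift: RigidTransform,
    scan_sigma: float = 0.0,
    landmark_sigma: float = 0.0,
    seed: int = 0,
    spacing: float = 1.0,
    icp: IcpParams | None = None,
):
    """CT-to-CT drift study on one phantom; returns a metrics dict.

    Pre- and post-operative CT volumes are voxelized from the phantom before
    and after the injected drift, segmented to surface and skeleton models,
    and the two surface models are registered (the registration cloud is the
    post-operative surface vertices, optionally perturbed by ``scan_sigma``
    Gaussian noise). Surface and skeletal drift are measured residual to
    that registration.
    """
    rng = np.random.default_rng(seed)
    skin, bone, lms = make_phantom(spec)
    skin2, bone2, truth = inject_drift(skin, bone, surface_shift, extra_bone_shift)

    vol_pre = voxelize_ct(skin, bone, spacing)
    vol_post = voxelize_ct(skin2, bone2, spacing)
    pre_surf = segment_preset(vol_pre, "surface")
    pre_bone = segment_preset(vol_pre, "skeleton")
    post_surf = segment_preset(vol_post, "surface")
    post_bone = segment_preset(vol_post, "skeleton")

    cloud_pts = post_surf.vertices
    if scan_sigma > 0:
        cloud_pts = cloud_pts + rng.normal(0.0, scan_sigma, cloud_pts.shape)
    lm_post = surface_shift.apply(lms)
    if landmark_sigma > 0:
        lm_post = lm_post + rng.normal(0.0, landmark_sigma, lm_post.shape)

    icp = icp or IcpParams(subsample_size=3000, seed=seed)
    res = register_two_step(PointCloud(cloud_pts), pre_surf, (lms, lm_post), icp)

    surf_rep = drift_field(
        pre_surf, post_surf, res.total,
        source_label="preoperative CT surface", target_label="postoperative CT surface",
    )
    skel_rep = skeletal_drift(pre_bone, post_bone, res.total)
    return {
        "registration_rms_mm": float(res.rms),
        "registration_converged": bool(res.converged),
        "surface_drift_mean_mm": float(surf_rep.mean),
        "surface_drift_rms_mm": float(surf_rep.rms),
        "skeletal_drift_mean_mm": float(skel_rep.mean),
        "skeletal_drift_max_mm": float(skel_rep.max),
        "injected_bone_shift_mm": truth["extra_bone_translation_mm"],
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the combined report dict.

    Artifacts land under ``cfg.outdir``. Raises :class:`PipelineError`
    naming the failing stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": yaml.safe_load(cfg.to_yaml())}

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        log.info("stage %s", stage)
        spec = PhantomSpec(seed=cfg.seed)
        skin, bone, lms = make_phantom(spec)
        vol = voxelize_ct(skin, bone, cfg.spacing)
        volume_path = outdir / "ct.nii.gz"
        pio.write_volume(vol, volume_path)
        pio.write_mesh(skin, outdir / "skin_true.stl")
        pio.write_mesh(bone, outdir / "bone_true.stl")
        g_intra = RigidTransform(
            rotation_about_axis(cfg.intra_rotation_axis, cfg.intra_rotation_deg),
            np.asarray(cfg.intra_translation, dtype=float),
        )
        cam = SliCameraSpec(
            fov_deg=cfg.scan_fov_deg,
            width=cfg.scan_width,
            height=cfg.scan_height,
            noise_sigma=cfg.scan_noise_sigma,
            seed=cfg.seed,
        )
        scan_ct_frame = simulate_sli(skin, cam)
        scan = PointCloud(g_intra.apply(scan_ct_frame.points))
        pio.write_point_cloud(scan, outdir / "scan.ply")
        rng = np.random.default_rng(cfg.seed + 1)
        lm_sli = g_intra.apply(lms)
        if cfg.scan_noise_sigma > 0:
            lm_sli = lm_sli + rng.normal(0.0, cfg.scan_noise_sigma, lm_sli.shape)
        pio.write_landmarks(lms, lm_sli, outdir / "landmarks.txt")
        _write_json(outdir / "truth.json", {
            "intra_pose": {"rotation": g_intra.rotation.tolist(),
                           "translation": g_intra.translation.tolist()},
            "n_scan_points": len(scan),
        })
        report[stage] = {"n_scan_points": len(scan), "volume_shape": list(vol.shape)}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(e)) from e

    # -- segment -----------------------------------------------------------
    stage = "segment"
    try:
        log.info("stage %s", stage)
        vol_path = Path(cfg.volume) if cfg.volume else volume_path
        if not vol_path.exists():
            raise FileNotFoundError(f"volume not found: {vol_path}")
        vol = pio.read_volume(vol_path)
        surface = segment_preset(vol, "surface")
        skeleton = segment_preset(vol, "skeleton")
        pio.write_mesh(surface, outdir / "surface.stl")
        pio.write_mesh(skeleton, outdir / "skeleton.stl")
        report[stage] = {
            "surface_vertices": len(surface.vertices),
            "skeleton_vertices": len(skeleton.vertices),
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # -- register ----------------------------------------------------------
    stage = "register"
    try:
        log.info("stage %s", stage)
        ct_lms, sli_lms = pio.read_landmarks(outdir / "landmarks.txt")
        res = register_two_step(
            scan, surface, (ct_lms, sli_lms), cfg.icp_params(),
            quality_threshold=cfg.quality_threshold, max_restarts=cfg.max_restarts,
        )
        _write_json(outdir / "registration.json", {**res.to_dict(), "seed": cfg.seed})
        report[stage] = {
            "rms_mm": float(res.rms),
            "iterations": int(res.iterations),
            "converged": bool(res.converged),
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # -- track-tube --------------------------------------------------------
    stage = "track-tube"
    try:
        log.info("stage %s", stage)
        # plan: enter above the bone at mid-length, aim at the bone axis
        spec0 = PhantomSpec(seed=cfg.seed)
        zmid = spec0.length / 2.0
        bx, by = spec0.bone_offset
        entry_r = spec0.skin_radius(0.0, zmid)
        path_ct = plan_path([float(entry_r), 0.0, zmid], [bx, by, zmid])
        entry_sli = g_intra.apply(path_ct.entry)
        target_sli = g_intra.apply(path_ct.target)
        path = plan_path(entry_sli, target_sli)
        _write_json(outdir / "path.json", {
            "entry": entry_sli.tolist(), "target": target_sli.tolist(),
        })
        # guiding tube held on the planned axis, proximal end at the entry
        tube_center = path.entry - (cfg.tube_length / 2.0) * path.direction
        tube_true = CylinderModel(
            center=tube_center, axis=path.direction,
            radius=cfg.tube_radius, length=cfg.tube_length,
        )
        tube_cloud, _ = make_tube_cloud(
            tube_true, angular_coverage=180.0, n=2000,
            noise_sigma=cfg.scan_noise_sigma, outlier_fraction=0.1, seed=cfg.seed,
        )
        pio.write_point_cloud(tube_cloud, outdir / "tube.ply")
        model, inliers = fit_cylinder_ransac(
            tube_cloud,
            RansacParams(
                distance_threshold=cfg.ransac_threshold,
                max_iterations=cfg.ransac_iterations,
                seed=cfg.seed,
            ),
        )
        dev = path_deviation(model, path)
        ok, msg = check_tolerance(dev, cfg.tolerance_angle_deg, cfg.tolerance_offset_mm)
        _write_json(outdir / "deviation.json", {
            **dev.to_dict(),
            "within_tolerance": bool(ok),
            "message": msg,
            "fitted": {
                "center": model.center.tolist(), "axis": model.axis.tolist(),
                "radius_mm": model.radius, "length_mm": model.length,
            },
            "n_inliers": int(inliers.sum()),
            "seed": cfg.seed,
        })
        report[stage] = {
            "angle_deg": dev.angle,
            "lateral_offset_mm": dev.lateral_offset,
            "within_tolerance": bool(ok),
            "fitted_radius_mm": model.radius,
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # -- drift -------------------------------------------------------------
    stage = "drift"
    try:
        log.info("stage %s", stage)
        g_post = RigidTransform(
            rotation_about_axis([0.0, 0.0, 1.0], cfg.postop_rotation_deg),
            np.asarray(cfg.postop_translation, dtype=float),
        )
        e_bone = RigidTransform.from_translation(cfg.extra_bone_translation)
        metrics = drift_rehearsal(
            PhantomSpec(seed=cfg.seed), g_post, e_bone,
            scan_sigma=cfg.scan_noise_sigma, landmark_sigma=cfg.scan_noise_sigma,
            seed=cfg.seed + 2, spacing=cfg.spacing,
        )
        _write_json(outdir / "drift.json", metrics)
        report[stage] = metrics
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # -- summarize ---------------------------------------------------------
    stage = "summarize"
    try:
        log.info("stage %s", stage)
        table = load_reference_table()
        summary = {}
        for col in ("rms_ct_sli", "rms_ct_ct", "surface_drift", "skeletal_drift"):
            s = cohort_summary(table[col])
            summary[col] = {"n": s.n, "mean": s.mean, "sd": s.sd}
        d1, t1, p1 = paired_difference(table["rms_ct_ct"], table["rms_ct_sli"])
        d2, t2, p2 = paired_difference(table["skeletal_drift"], table["surface_drift"])
        summary["paired_ct_ct_minus_ct_sli"] = {"mean": d1.mean, "sd": d1.sd, "t": t1, "p": p1}
        summary["paired_skeletal_minus_surface"] = {"mean": d2.mean, "sd": d2.sd, "t": t2, "p": p2}
        _write_json(outdir / "summary.json", summary)
        report[stage] = summary
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    _write_json(outdir / "report.json", report)
    return report
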