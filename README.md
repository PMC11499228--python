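# punctnav

Computational core of a **CT + structured-light imaging (SLI) guided
orthopedic puncture navigation system**, for researchers and engineers
building or evaluating image-guided intervention pipelines.

The clinical problem: surgical navigation maps a preoperative CT plan
(virtual space) onto the intraoperative scene (real space). Any change in
that mapping during surgery — *image drift and mismatch* — directly degrades
puncture accuracy. This toolkit implements the software side of a workflow
that fights drift with a rigid polymer-bandage fixation of the limb, dense
structured-light surface scanning, and continuous quantitative feedback:

1. **Navigation map** (`punctnav.ct_modeling`): threshold segmentation of the
   CT volume (body surface −650 HU→max, skeleton 125 HU→max), largest
   connected component, marching-cubes surface extraction, puncture-path
   planning, and the bandage strapping-length rule `L = 2D + 10` (cm).
2. **Registration** (`punctnav.registration`): the intraoperative SLI cloud
   is aligned to the CT surface model in two steps — closed-form landmark
   (Kabsch/SVD) coarse alignment on the conspicuous bandage-fixture
   features, then a trimmed, subsampled ICP refinement against the mesh.
   The CT model is mapped to scanner coordinates as `M_SLI = R·M_CT + T`,
   with the total transform the exact composition of the coarse and fine
   steps, gated by the distance test function (full-cloud nearest-surface
   RMS) with restarts.
3. **Tube tracking** (`punctnav.tube_tracking`): a cylinder is fitted to the
   guiding-tube scan by two-point-with-normals RANSAC (axis = cross product
   of surface normals) with least-squares polish, then scored against the
   planned path: angle, lateral offset, tip gap, and an inclusive
   pass/fail tolerance gate.
4. **Drift assessment** (`punctnav.drift`): nearest-surface distance fields
   between registered surfaces (RMS/mean/SD/max, PLY heat-map export);
   skeletal drift measured residual to the surface registration; cohort
   statistics as mean ± sample SD with paired t-tests. The 20-specimen
   benchmark table of registration RMS and drift values ships with the
   package.
5. **Phantom simulator** (`punctnav.phantom`): analytic limb-like phantoms,
   CT voxelization (air/soft-tissue/bone at −1000/40/700 HU), a pinhole
   structured-light scan simulator with depth noise and dropout, partial
   tube clouds with planted outliers, and known-drift injection — every
   stage has a generate-and-recover test with exact ground truth.

Exact geometry throughout: point-to-mesh distances are computed by KD-tree
candidate pruning with an exactness guarantee (no approximate neighbours),
because drift at the 0.03 mm scale leaves no room for approximation error.

See `docs/methods.md` for the models, parameter defaults, and limitations.

## Worked example

Run the full desk-scale rehearsal — simulate a phantom, voxelize a CT,
segment it, scan it, register, track the guiding tube, inject a 0.3 mm bone
drift and measure it:

```bash
punctnav pipeline --outdir run --seed 0
```

which prints (abridged):

```json
{
 "register": { "converged": true, "iterations": 100, "rms_mm": 0.2095 },
 "track-tube": { "angle_deg": 0.0145, "lateral_offset_mm": 0.0124,
                 "fitted_radius_mm": 4.9907, "within_tolerance": true },
 "drift": { "registration_rms_mm": 0.2848,
            "surface_drift_mean_mm": 0.2009,
            "skeletal_drift_mean_mm": 0.2890,
            "injected_bone_shift_mm": 0.3 }
}
```

Reading the numbers: the scan registered to the CT surface with 0.21 mm RMS
(sub-millimetre, so the quality gate at 1 mm passes on the first attempt);
the fitted guiding tube is 0.01° / 0.01 mm off the planned path — well
inside the 3° / 2 mm intraoperative tolerance; and the CT-to-CT drift study
recovers the injected 0.3 mm bone shift as a 0.29 mm mean skeletal drift,
clearly exceeding the 0.20 mm surface drift floor, reproducing the study's
qualitative finding that bone drifts more than the immobilised surface.

The cohort statistics of the packaged 20-specimen benchmark table:

```bash
punctnav summarize --out summary.json
```

gives `rms_ct_sli` 0.575 ± 0.146 mm, `rms_ct_ct` 0.407 ± 0.234 mm,
`surface_drift` 0.033 ± 0.027 mm, `skeletal_drift` 0.235 ± 0.197 mm, and the
paired differences −0.169 mm (CT-CT minus CT-SLI) and 0.202 mm (skeletal
minus surface), both significant at p < 0.05.

Individual stages are available as subcommands (`simulate`, `segment`,
`register`, `track-tube`, `drift`, `summarize`, `config`) and as plain
library calls; `punctnav config --dump` prints every default.

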