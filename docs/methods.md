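# Methods

`punctnav` re-implements the computational core of a CT + structured-light
imaging (SLI) guided orthopedic puncture navigation workflow: a preoperative
CT navigation map, registration of intraoperative surface scans to it,
guiding-tube tracking by cylinder fitting, and quantitative drift
assessment. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show about
real data.

## Coordinate conventions and the rigid-transform model

All geometry is in millimetres in a right-handed world frame. A rigid
transform maps points as `p' = R p + t` with `R` a proper rotation
(orthonormal, det +1, both enforced to 1e-8). Volumes use the voxel-center
convention: the world position of voxel index `(i, j, k)` is
`origin + index * spacing`, 0-based.

The registration chain composes a coarse feature-match transform
(`R_FM, T_FM`) with a fine ICP correction (`R_ICP, T_ICP`). The toolkit
composes transforms exactly — `R = R_ICP R_FM`, `T = R_ICP T_FM + T_ICP` for
coarse-then-fine application — because the additive translation convention
`T = T_FM + T_ICP` sometimes quoted for such chains is exact only when the
fine rotation is the identity. The additive rule is retained as a documented
`mode="legacy"` of `compose_transforms` and agrees with the exact rule
whenever the second step is a pure translation; correctness of the pipeline
never depends on the fine step being near-identity.

## Nearest-distance queries (the distance test function)

Registration quality and all drift metrics reduce to per-point
nearest-distance queries. Both variants are exact, not approximate:

- point-to-cloud: KD-tree (`scipy.spatial.cKDTree`) exact nearest
  neighbour;
- point-to-mesh: exact closest-point-on-triangle evaluated over a candidate
  set gathered by KD-tree search on triangle centroids. A per-mesh
  circumradius bound guarantees the search cannot terminate while a nearer
  triangle remains unexamined, so the result equals the exhaustive minimum.
  Triangles with outsized circumradius (end-cap fans, for example) are
  bisected at build time — the union of the pieces is the same surface, so
  distances are unchanged while the pruning bound stays tight.

Drift values at the 0.03 mm scale cannot tolerate approximate neighbours,
which is why no approximate spatial index is used anywhere. Tests
cross-check against brute-force `O(N·M)` oracles.

Whether the published workflow's distance test is point-to-point or
point-to-surface is not stated; both are available, and point-to-surface is
the default (and the stricter reading) wherever a mesh is on one side.

## CT navigation map

Segmentation is plain Hounsfield thresholding with the two clinical
presets: body surface −650 HU to maximum, skeleton 125 HU to maximum. The
interactive mask clean-up of a clinical workstation (region growing, mask
editing) is replaced by deterministic largest-connected-component selection
(6/18/26-connectivity, default 26) plus optional morphological closing
(default radius 1 voxel), so the pipeline is reproducible without an
operator. Surfaces come from marching cubes at the 0.5 level of the binary
mask — the thresholds remain the single source of truth for the geometry.

One consequence worth knowing: a binary-mask isosurface carries a staircase
artifact that inflates the *area* of curved surfaces by roughly 8% (a
voxelized sphere reads ~8.5% high) while leaving enclosed volume essentially
unbiased (<2%). No smoothing is applied by default; `extract_surface`
accepts `smooth_sigma` (voxels) to pre-smooth the occupancy field when an
area-faithful surface matters more than preserving sub-voxel features.

Volumes are consumed as NIfTI (.nii/.nii.gz) via nibabel; DICOM transport is
out of scope (standard converters exist). Meshes are written as binary STL
or PLY via trimesh. The polymer-bandage strapping-length rule `L = 2D + 10`
(centimetres, `D` the limb diameter) is provided as a planning utility.

## Two-step registration

Coarse alignment consumes explicit landmark correspondences — the
conspicuous features on the bandage fixtures, picked in both CT and scanner
frames — and solves the least-squares rigid transform in closed form
(centroid alignment + SVD with determinant correction). At least three
non-collinear pairs are required.

Fine alignment is a speed-up flavour of ICP: a random subsample of the
source cloud (drawn once per run; default 5,000 points), exact
nearest-point correspondences against the target mesh via the spatial
index above, distance-trimmed correspondences (default trim fraction 0.2,
plus an optional hard `max_pair_distance` gate), and the closed-form SVD
update, iterated until the trimmed RMS changes by less than `rel_tolerance`
(default 1e-6) or `max_iterations` (default 100) is reached. With the
subsample fixed and trimming by count, the per-iteration trimmed RMS is
provably non-increasing, and the suite asserts that on every run. Trimming
buys outlier robustness at a price: because it also discards the
largest-distance *genuine* correspondences, the final fraction of a
millimetre is approached slowly, and tight recovery targets need the
iteration budget.

`register_two_step` gates the result on the distance test function — the
RMS of nearest-surface distances of the full (non-subsampled) cloud against
the transformed CT model, the strictest reading of a single per-specimen
RMS. If the RMS exceeds `quality_threshold` the refinement restarts with a
fresh subsample seed, up to `max_restarts` (default 3). The published
workflow never states its numeric acceptance threshold; the default here is
1.0 mm, chosen so that sub-millimetre phantom registrations pass while
gross failures restart, and it is exposed in the configuration.

A caution that the phantom studies make vivid: ICP alone, started from the
identity on a one-sided scan of a near-cylindrical limb segment, can stall
in a shallow valley where the surface slides along itself. The coarse
landmark step exists precisely to remove that failure mode; the fine step
is only asked to polish a roughly correct pose.

## Tube tracking

The guiding tube appears to the camera as a partial strip of cylinder
(roughly half the circumference). Normals are estimated per point as the
smallest eigenvector of the k-nearest-neighbour covariance (default k=12),
oriented toward a configurable viewpoint. RANSAC hypotheses come from
minimal two-point samples: the axis is the normalised cross product of the
two surface normals (parallel-normal pairs are skipped), the axis point is
the midpoint of the common perpendicular of the two normal lines, and the
radius is the mean point-to-axis distance. Inliers satisfy
`|distance-to-axis − radius| ≤ distance_threshold` (default 0.6 mm); the
best consensus model is polished by Levenberg–Marquardt over its inliers
(axis point offsets in the normal plane, two tilt angles, radius), and the
returned inlier flags are re-scored against the polished model so they are
exactly reproducible from it. Length is the extent of inlier projections on
the axis; the centre is the midpoint of that extent. Fits are stable down
to roughly 120 degrees of angular coverage; below that the radius/axis
trade-off degrades — a documented limitation.

Deviation from the planned path is reported as three quantities a surgeon
can act on: the orientation-agnostic angle between tube axis and planned
direction, the lateral offset from the planned entry point to the tube axis
line, and the gap from the nearer tube end to the entry point. The
intraoperative tolerance gate defaults to 3 degrees and 2 mm (inclusive);
no published tolerance exists, so these are configuration defaults, not
constants.

## Drift assessment

Drift between two surface models is the nearest-surface distance field of
the moving model against the reference, summarised as RMS, mean, sample SD
and max. Skeletal drift is measured *residual to the surface registration*:
the preoperative bone is carried through the transform obtained by
registering the surfaces, and its remaining distance to the postoperative
bone is the drift of bone relative to the immobilised surface.

Nearest-surface distance is correspondence-free and one-sided, and that has
a quantitative consequence: where a surface slides tangentially along
itself under a displacement (a tube translated across its axis), per-point
distances shrink toward zero, so the *mean* of a drift field is a lower
bound on the physical displacement. For a circular-section bone shifted
laterally by `d`, the mean reads approximately `(2/π)·d` while the maximum
still attains `d` where the surface normal aligns with the motion. Exact
mean recovery of an injected shift therefore only holds on locally planar
geometry normal to the shift — the validation suite uses a planar bone
stand-in for the exact check and the realistic curved phantom, through the
full noisy CT-to-CT pipeline, for recovery at the 0.2 mm level. Published
per-specimen drift numbers measured this way inherit the same property.

Cohort statistics are mean ± sample standard deviation (n−1). The sample
convention is deliberate: recomputing the packaged 20-specimen benchmark
table reproduces its printed SD of 0.146 only with the n−1 denominator
(population SD gives 0.142). Display rounding is 3 decimals, half away from
zero; raw values are retained internally. Paired comparisons report the
mean ± SD of element-wise differences plus the paired t statistic (n−1
degrees of freedom) with a two-sided p-value; t is reported as
not-applicable when the differences have zero variance. Two known
inconsistencies in the published table are documented rather than matched:
the surface-drift SD prints as 0.272 while its own 20 rows give ≈0.027, and
the first column's mean prints as 0.576 while the 3-decimal rows give
0.57545 (displaying as 0.575); recomputed values are reported as computed.

Heat maps are written as PLY with the raw distances in a per-vertex
`quality` property (lossless round trip) and an 8-bit colour ramp clamped
to a configurable range (default 0–1 mm).

## The phantom: what it emulates and what it does not

The synthetic phantom stands in for the cadaver specimens and the SLI
hardware so that every stage has a generate-and-recover test with known
ground truth:

- **Geometry.** A limb-like segment: tapered elliptical skin (default
  proximal radii 45 × 38 mm, length 160 mm, distal taper 0.85) with six
  raised knobs (3 mm) emulating the conspicuous bandage-fixture features —
  their apexes are the coarse-registration landmarks — and an off-centre
  tubular bone (radius 12 mm, offset (8, 5) mm, low-order surface bump)
  kept at >2 mm clearance inside the skin. All shapes are analytic, so an
  exact interior test independent of any mesh is available as an oracle.
- **CT.** Voxelization assigns the three intensity classes the thresholds
  expect: air −1000 HU, soft tissue 40 HU, bone 700 HU, on a configurable
  grid (1 mm default, against the scanner's 0.675 mm slice thickness).
  Interiors are rasterized by even-odd parity counting of triangle
  crossings along voxel columns, with a sub-micrometre deterministic offset
  of the sample positions so rays never pass exactly through vertices.
- **SLI.** The structured-light decoder is not simulated; the generator
  produces its *output*: a pinhole camera (default mounted 1.2 m away,
  30-degree field of view, mimicking the 0.9–1.5 m working distance of the
  real head) casts one ray per grid cell, keeps first intersections only
  (hidden surfaces absent), perturbs each point along its ray with Gaussian
  depth noise (default σ = 0.1 mm, consistent with a sub-millimetre
  system), and drops a configurable fraction of points. Ray-triangle
  intersection is exact Möller–Trumbore; candidate pairs come from
  rasterising projected triangle bounding boxes into the pixel grid.
- **Tube scans** sample a configurable angular sector of the cylinder with
  radial Gaussian noise plus a planted fraction of uniform box outliers,
  returning ground-truth inlier flags.
- **Drift injection** moves the skin by one rigid transform and the bone by
  that transform composed with an extra bone shift, returning the ground
  truth for recovery tests.

Everything is bit-reproducible given (spec, seed).

What passing these tests does *not* show: the phantom is rigid, so nothing
is learned about soft-tissue deformation, bandage mechanics, or drill
forces; the noise model is isotropic Gaussian depth noise, not the
structured, surface-angle-dependent error of a real fringe-projection
camera; CT is an ideal three-class voxelization with no beam hardening,
motion artifacts or partial-volume blur; and cross-modality intensity
discrepancies between CT-derived and optical surfaces are absent. The
phantom validates the *algorithms* under controlled conditions, not the
hardware error budget of the physical system.

## Study sizes and numerical choices

The validation studies use desk-scale problem sizes chosen to exercise the
estimators well inside their asymptotic regime: scans of ~5,500 points
(160×120 rays at 12-degree field of view), 20-seed Monte-Carlo for
registration (scan noise σ = 0.3 mm, landmark noise σ = 0.5 mm, poses up to
5 degrees / 5 mm) and for cylinder recovery (σ = 0.2 mm, 25% outliers, 180
degrees coverage, n = 2,000), 10-seed CT-to-CT drift rehearsals at 1 mm
voxels, and a 0.3 mm injected bone shift. Degenerate inputs (empty masks,
collinear landmarks, all-outlier clouds, coincident path points) raise
typed errors rather than returning garbage; boundary tolerance checks are
inclusive; ICP stops early at machine-zero RMS (<1e-9 mm) since there is
nothing left to refine.

## Known limitations

- Registration is rigid only; no scale, affine or deformable extension.
- Landmark correspondences are consumed as given; there is no automatic
  feature detector for real scans (the phantom generator returns its knob
  apexes, which is a best-case correspondence quality).
- Trimmed ICP converges slowly in its last fraction of a millimetre (see
  above); budget iterations accordingly.
- Cylinder fits need ≥120 degrees of angular coverage and reliable normals;
  very sparse or grazing tube scans degrade first in radius.
- The mean of a nearest-surface drift field under-reports tangential
  motion; read it together with the max, or against locally planar
  geometry.
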