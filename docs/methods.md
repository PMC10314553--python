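# Methods

## Data model and conventions

All geometry lives in RAS millimetres (+X patient-right, +Y anterior, +Z
superior). Readers convert on load: NIfTI volumes are reoriented to
canonical RAS axis order and binarized at 0.5; Slicer fiducial files are
converted from LPS when their header declares it (FCSV `# CoordinateSystem`,
markups-JSON `coordinateSystem`; LPS is assumed for markups JSON without the
field, matching Slicer's default). Free-text fiducial labels map to
canonical names (Ba, PNS, C2I, C4S, CoR/CoL, GoR/GoL, B, PoR/PoL, OrR/OrL)
through an editable alias table.

## Head frame

The oriented frame is fully determined by three constraints: the
transporionic axis defines X; the Frankfurt plane through the two porions
and the *mean* of the left/right orbitale defines Z (averaging reduces four
points to three, making the plane — and hence the frame — deterministic
rather than a least-squares compromise); Y completes the right-handed triad.
The origin is the mid-transporionic point. Degenerate configurations
(coincident porions, collinear Po/Or) raise rather than silently producing
an arbitrary frame.

## Registration

Two strategies with one contract: express T1 in the oriented T0 frame.

- **Landmark** (default): the closed-form orthogonal-Procrustes rigid fit
  over cranial-base landmarks (Ba, PNS, Po, Or — structures treatment does
  not move). Deterministic, exact for noise-free rigid motion; a fit whose
  optimum would be a reflection is rejected as unphysical. If fewer than
  three cranial-base landmarks are shared, all shared landmarks are used —
  appropriate whenever their inter-timepoint motion is rigid (e.g.
  phantoms).
- **Voxel**: rigid registration of the masks themselves. Binary inputs are
  Gaussian-smoothed (default 1.5 mm) into soft edge maps; normalized
  correlation is maximized over a 3-level multi-resolution pyramid with
  regular-step gradient descent and dense sampling, so results are
  reproducible for fixed settings. A cranial-base region mask, when given,
  restricts the metric. On asymmetric phantoms, programmed motions with
  |t| ≤ 5 mm and angles ≤ 6° are recovered to ≲0.1 mm / ≲0.3°, comfortably
  inside the 0.5 mm / 0.5° acceptance band.

Registration error is reported as mean displacement over a point cloud plus
rotation-angle difference: comparing raw translation vectors conflates the
choice of rotation centre with true misregistration.

Masks are resampled by nearest-neighbour onto the fixed grid (binarity is
preserved exactly; volume drift is measured in tests). Round-trip
transform-then-invert Jaccard is ≥ 0.98 at ≤ 0.5 mm voxels for the smooth
tube phantom; coarser grids or motions that push anatomy outside the field
of view degrade this, which is a property of any resampling scheme.

## Airway regions

The delimiting "Ba–PNS plane" is under-determined by two points; it is made
unique by requiring perpendicularity to the midsagittal plane: the unit
normal lies in the YZ plane, orthogonal to the YZ-projection of Ba→PNS,
with positive Z component. C2I and C4S planes share that normal. Plane
ordering (base above C2I above C4S) is validated.

**Volumes** count foreground voxel centres in half-open slabs `[lower,
upper)` times the voxel volume. No partial-volume weighting: the estimator
is exactly additive (superior + inferior = total voxel-by-voxel) and
exactly reproducible. The price is an O(h) boundary error with two parts:
cross-section discretization (~0.1–0.5% at 0.4–0.5 mm for a 10 mm-radius
duct) and ±1-slice quantization where a slab boundary falls between voxel
layers (up to h/2 ÷ region height; ~0.8% for a 25 mm region at 0.4 mm).
Because of the second term, convergence as the voxel shrinks is monotone
only in the mean over grid alignments and only across voxel sizes
commensurate with the region height — the tests measure it that way. The
phantom generator deliberately offsets its grid by an irregular sub-voxel
amount so that voxel centres are not symmetric with respect to the
boundaries (symmetric alignments produce systematic tie artifacts).

**Surface areas** come from one triangulated iso-surface of the whole mask
(marching cubes at level 0.5), with triangles assigned to slabs by centroid
— stacked slabs therefore partition the total area. Planar cut caps are not
added: the area is meant to measure airway wall, not the artefact of
delimitation. The binary grid is Gaussian-smoothed by one voxel before
triangulation: raw binary marching cubes produces a 45°-facet staircase
that overestimates the lateral area of a 10 mm cylinder at 0.4 mm voxels by
~6.7%, far outside tolerance, while the one-voxel-smoothed surface is
accurate to ~0.1% (and ~1% at 0.8 mm). Under a common rigid motion of mask
plus landmarks, volumes are stable to <0.5% and areas to ~0.6%
(resampling-limited).

## Mandibular kinematics

"Pitch" is defined by projection: each directed line (Co→Go, Co→B) is
projected onto the midsagittal YZ plane and its orientation angle
θ = atan2(Δz, Δy) tracked from T0 to T1; the rotation is wrap(θ₁ − θ₀) to
(−180°, 180°]. The projection gives pitch a sign — positive
counterclockwise from the patient's right — which the 3D angle between
lines cannot; the sign carries the clinically meaningful distinction
between bite-opening (clockwise, negative) and counterclockwise rotation
patterns. For any pure pitch rotation about an axis ∥ X, all four line
pitches equal the programmed angle to 1e-6°; pure translations read as
zero. The projection is invariant to common pitch+translation motions of
both timepoints but not to arbitrary common yaw/roll (a 90° common yaw
degenerates the projection), which is why measurement happens in the
oriented head frame. Lines parallel to the X axis have no sagittal
direction and raise a degeneracy error. Left and right sides are reported
separately and averaged; the paired left-vs-right t test in the statistics
layer is the check that pooling is justified.

## Reliability

Dahlberg's d = √(Σd²ᵢ/2n) estimates the per-session random error σ when
both sessions carry i.i.d. noise. The relative error uses the grand mean of
both sessions as denominator — symmetric in the sessions, whereas "the
original measure" alone would privilege one. The ICC defaults to the
two-way mixed, consistency, single-measurement form ICC(3,1), the standard
choice when the same single rater performs both sessions and rater is a
fixed effect; ICC(2,1) (absolute agreement, penalizing a systematic session
shift) is a configuration option. Both are computed from the explicit
two-way ANOVA mean squares and cross-checked in tests against an
independent implementation.

## Cohort statistics

- Student t between groups uses pooled variance — the named test — with
  Welch as an option; summary-statistics input `(n, mean, sd)` is accepted
  so printed tables can be re-tested.
- KS normality with estimated parameters uses a seeded Monte-Carlo
  Lilliefors p (default 10⁴ replicates): the textbook KS null is
  anticonservative when μ, σ are estimated from the sample. The +1-corrected
  Monte-Carlo p is exchangeable-valid and slightly conservative (measured
  null rejection 4.3% at α = 5%).
- The age adjustment is ANCOVA, `y ~ group + age` with Type II F tests —
  the natural reading of a "multifactorial" adjustment with a continuous
  covariate; its two p-values are calibrated (uniform under the null).
- χ² on 2×2 tables omits the continuity correction; with correction the
  printed sex-split p of the reference cohort (0.492 from 9/8 vs 7/10) is
  not reproducible.
- Sample size for the paired design searches the smallest n whose two-sided
  noncentral-t power reaches the target; power is monotone in n so the
  search is exact. No multiple-testing correction is applied anywhere; the
  study report logs how many tests it ran.

Monte-Carlo experiments in the tests spawn independent substreams from one
root `SeedSequence` rather than using consecutive integer seeds; the latter
produce detectably non-uniform leading draws across streams.

## Synthetic data

The generators stand in for clinical CBCT data and define the validation
conditions:

- **Airway phantom**: a voxelized tube (piecewise-constant radius, axis ∥ Z)
  with Ba/PNS on the — optionally tilted — base plane and C2I/C4S at their
  levels. For planes sharing a tilted normal, the slab volume is
  πr² × (axial height) and the lateral area 2πr × (axial height), so ground
  truth stays closed-form even for oblique cuts. Defaults: r = 10 mm, 25 mm
  superior and inferior segments, 0.4 mm voxels — the scale and resolution
  of the clinical scans the pipeline targets.
- **Mandible case**: a landmark template moved by a programmed pitch about
  the mid-condylar axis plus AP/SI translation; truth is exact forward
  kinematics.
- **Jittered landmarkings**: i.i.d. isotropic Gaussian relocation error per
  landmark and repeat (σ = 0.3 mm in the reliability tests, the order of
  published intra-rater relocation error).
- **Cohort simulator**: change scores drawn multivariate-normal with
  per-group means/SDs and a target correlation matrix (Cholesky; non-PD
  targets are rejected); T1 = T0 + change with independently drawn T0.
  Defaults reproduce the reference study's conditions: n = 17 per group,
  published T0 means/SDs and change means for the six airway measures and
  four mandibular measures, published demographics (BMI computed from drawn
  weight and height, so manifests are self-consistent). Change SDs for the
  airway variables are not published and are derived from the T0/T1 SDs
  under an assumed longitudinal correlation ρ = 0.8, a typical test–retest
  value for anatomical volumes. The published pairwise correlations of the
  MMA group are not jointly realizable as a correlation matrix; the MMA
  default is the nearest valid matrix (Higham projection, frozen in the
  source), while the MAD defaults are realizable as printed.

What the phantoms do *not* emulate: gray-scale CBCT appearance, scatter and
motion artefacts, segmentation error against ground-truth anatomy, airway
shape irregularity, and soft-tissue deformation between timepoints. Passing
phantom tests therefore demonstrates correctness of the geometry,
kinematics and statistics pipeline — not the accuracy of any upstream
segmentation.

## Problem sizes used in validation

Phantom volumetric closure runs at the native 0.4 mm voxel size; shared
fixtures use 0.8 mm where sub-voxel accuracy is not the point. Voxel
registration recovery uses 20 programmed motions at 0.8 mm on an
asymmetric multi-ellipsoid phantom (a tube is rotationally ambiguous).
Statistical calibration uses 2000 null cohorts (type-I error), 500 cohorts
for correlation recovery, and 500 model fits for ANCOVA null uniformity.

## Known limitations

- Voxel-centre volume counting has O(h) boundary error; at coarse grids
  (≥ 0.8 mm) the ±1-slice slab quantization can reach a few percent of a
  25 mm region.
- Surface areas exclude cut caps by design; tools that include them will
  report systematically larger areas (by exactly the cap areas).
- The anatomical definitions of the C2I/C4S levels are taken as given
  landmark points; no vertebral geometry is inferred.
- The voxel registration models a 6-DOF rigid motion only; growth or
  deformation between timepoints is outside the model and will surface as
  residual metric value, not as a warning.
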