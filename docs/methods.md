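# Methods

## Coordinate conventions

All geometry lives in a right-handed patient frame in millimetres:
+X medial→lateral pointing to the patient's left (right leg at negative X,
midline at X = 0), +Y posterior→anterior, +Z inferior→superior.  Voxel
grids use the voxel-center convention with 0-based indices; frontal
projections integrate along Y (image u ↔ X), sagittal projections along X
(u ↔ Y); the image v axis runs top-down (−Z), shared between the two views
because the emitter translates vertically.

## Phantom model

A leg is assembled from analytic primitives: femur = capsule from the hip
center down to just above the knee plus a femoral-head sphere (hip center =
sphere center); tibia = capsule from knee to ankle center whose axis is
tilted by the varus angle in the frontal plane (positive = ankle deviates
toward the midline), capped by an elliptic plateau slab centred on the knee
whose outward normal is tilted posteriorly by the slope angle; a
soft-tissue capsule envelops each leg.  Intensities are piecewise constant
(soft 0.25, bone 0.9) — sufficient for line-integral radiographs; there is
no Hounsfield calibration, no cortical/trabecular texture, no
osteoarthritic plateau deformation, and the standing pose is fixed (these
are the main gaps between the phantom and real anatomy, so green tests
certify pipeline mechanics and geometry handling, not clinical image
realism).  The hip-to-knee share of leg length is 0.52.  The analytic
ground truth (MA = varus angle, TS = slope angle) comes from the
constructed landmarks and plane, never from re-measuring voxels.

Default dimensions (leg length 700 mm, shaft radii 14/12 mm, head radius
22 mm, plateau 60×45×14 mm, soft-tissue radius 45 mm, hip separation
200 mm) are chosen so a standing subject fits a 768 mm detector field and
the two soft-tissue silhouettes stay disjoint in the frontal view across
the cohort's deformity range.  Cohort variability: sizes drawn normal
(≈5–8% spread), varus uniform 2–10° and slope uniform 2–12° per leg —
ranges typical of an HTO (varus-malaligned) population.  The proximal-tibia
label covers tibia voxels within 120 mm of the knee center.

## Radiograph simulation

Parallel mode (the default) integrates intensity exactly along grid axes
and resamples onto the detector; fan mode traces per-row fans from a point
source (source–axis 1300 mm, axis–detector 300 mm — plumbing defaults, the
device's exact calibration being configurable) translated vertically, so
magnification acts only horizontally.  Images are min–max normalized to
[0, 1] with the original range kept in metadata (losses and linearity
checks can work pre-normalization).  The right-leg augmentation shifts
right-leg voxels and landmarks anteriorly by U(40, 60) mm and rotates them
by U(10°, 20°) (sign uniform — the clinical instruction does not fix one)
about the medial–lateral axis through the sagittal image center; the grid
is padded when the transform would leave it.  Separated-leg targets are
single-leg masked projections (retaining that leg's soft tissue) passed
through the logistic contrast transform with midpoint 0.45 and width 0.12.

Split arithmetic: test = round(0.10·n) with a minimum of one patient, then
val = round(0.20·pool), always at patient level so augmented copies never
straddle partitions; one split serves all networks.

## Networks

The three models run on a small reverse-mode NumPy engine (same-padded
3-kernel convolutions via sliding-window im2col + matmul, 2× max pooling,
nearest-neighbour upsampling, channel concatenation for skips, sigmoid /
per-voxel softmax heads, He-normal init, Adam).  Gradient checks against
finite differences and an exact conv adjoint identity are part of the test
suite.  Losses:

* separation: ½(MSE + (1 − L_GC)) per decoder, averaged over the two
  outputs.  L_GC is the mean of the NCCs of the horizontal and vertical
  central-difference gradient images (edges one-sided); a correlation is a
  similarity, so it enters the minimized loss as 1 − L_GC.  Zero-variance
  gradient images define L_GC = 0 with a warning.
* landmarks: mean binary cross-entropy with probabilities clipped at 1e−7.
* reconstruction: Dice loss over foreground classes plus cross-entropy.

The landmark and reconstruction nets backpropagate from the logits
(cross-entropy gradient p − y), the standard numerically safe formulation —
without it a saturated softmax kills the training signal for the ~1%
foreground fraction of the reconstruction target.

The reconstruction net follows the two-branch design: each view passes two
2D conv+pool levels; the S/4×S/4 maps are replicated S/4 times (frontal
along Y, sagittal along X), averaged voxel-wise into one fused 3D map, then
a 3D encoder/decoder (desk preset: two 3D levels) with skips on the fused
levels only.  A 512-pixel study yields a 128³ cube, the 128-pixel desk
preset a 32³ cube at detector pixel spacing.  Per-leg inputs are knee-
centred crops: a 32-pixel window centred 10 px below the knee (favouring
the proximal tibia), upsampled 4× to the 128-pixel network input; the
output cube covers the same world region.  The frontal landmark net emits
6 heatmap channels (both legs), the sagittal net 3; heatmaps are Gaussians
(σ = 5 px default) rescaled to peak 1.  Landmark decoding: argmax (ties to
the smallest (v, u)) refined by the centre of mass of a 7×7 window; an
all-zero channel reports "not detected".

The reference hyperparameters (kernel 3, pool 2, ReLU, 'same', He-normal,
Adam; per-net lr 0.001/0.0001/0.00005, epochs 20/20/30, batch 16/1/1) are
the defaults of the `full` preset.  The `desk` preset — 128 px detector at
6 mm, 32³ cubes, base width 4 (8 for landmark nets, 4 levels) — uses short
schedules sized for convergence on one CPU: reconstruction 3 epochs at lr
3e−3, frontal landmarks 45 epochs at 2e−3 (left/right disambiguation needs
absolute position, which a CNN learns slowly from border effects), sagittal
landmarks 10 epochs, separation 30 epochs with batch 4 (the desk train set
is ~30 studies; batch 16 would give only a handful of optimizer steps).
The measured desk experiment (40 phantoms, fixed seed) runs in ~7 minutes.

The desk ablation harness feeds the reconstruction net ground-truth
separated sagittals ("oracle separation") versus the raw superimposed
sagittal, isolating the information the separation step contributes
independent of separation-net training noise; the end-to-end pipeline uses
the trained separation net's outputs.

## Measurement

2D landmarks triangulate to 3D: in parallel mode X from the frontal u, Y
from the sagittal u, Z as the mean of the two v-derived heights; in fan
mode the least-squares midpoint of the two back-projected (per-row
horizontal) rays, with the ray gap returned as a residual.  MA is reported
as deviation from collinearity (0° = straight), positive = varus for the
measured side; TS positive = posterior slope.  Both are invariant to rigid
translation and uniform scaling.

The plateau plane fit selects mesh vertices within 8 mm of the most
superior vertex whose outward normals lie within 30° of +Z, fits by total
least squares, then iterates two refinements: reselect vertices whose own
normals agree with the running plane normal within 12°, and trim residual
outliers (>1 SD, floor 0.3 mm).  The refinements exist because the curved
plateau rim otherwise biases the fitted slope by 1–3°; the RMS residual is
attached to the plane as a quality flag, since plateau-plane fitting is the
dominant error source for TS.  Marching cubes (scikit-image) runs on the
one-voxel-padded binary field smoothed with a σ = 1 voxel Gaussian —
contouring the raw binary grid overestimates surface area by ~9%, the
smoothed field is within 1% on a voxelized sphere.  Mean surface distance
is the asymmetric prediction→truth mean of exact point-to-triangle
closest-point distances (own implementation: Ericson region tests over a
KD-tree candidate set with a radius guard that cannot miss the true closest
triangle; verified against a full scan).

## Planning

The plan vector: hinge position in the frontal plane (x, z — depth taken at
the knee-center Y), hinge direction as azimuth/elevation about the
anteroposterior axis, opening angle, cutting-plane inclination about the
hinge, and the plate pose (3 + 3).  The wedge opens medially: everything
distal to the cutting plane, including the ankle center, rotates rigidly
about the hinge axis, with the rotation sense chosen per side so positive
opening reduces varus.  The articular plane is cached from the (unmoved)
proximal fragment; achieved MA/TS are re-measured from the corrected
landmarks.  Note the opening needed to change MA by Δ exceeds Δ when the
hinge sits distal to the knee (shorter ankle lever arm) — the optimizer
absorbs this automatically.

Fitness = (|MA − Φ_MA|, |TS − Φ_TS|, mean plate-point distance to the
corrected bone surface); infeasible plans (hinge outside the bone, rule
violations) map to an all-infinite vector.  Default feasibility rules
(all thresholds configurable): hinge ≥ 10 mm from the lateral cortex
(probed in a ±6 mm band at hinge height), cut ≥ 15 mm below the plateau at
the knee center, plate footprint entirely on the medial cortex within the
bone's vertical extent.  These are a simplified, configurable stand-in for
a full clinical constraint catalogue.  Search bounds probe the cortex in
the hinge-height band below the plateau (the plateau is much wider than
the shaft, so global mesh extremes would waste most samples).

NSGA-II: simulated binary crossover (η = 15, p = 0.9), polynomial mutation
(η = 20, p = 1/12), binary tournament on (rank, crowding), feasible
initialization by rejection sampling with an error if no feasible
individual is found.  Defaults population 100 × 100 generations; the desk
preset uses 40 × 30 (the analytic opening-angle solution is found well
within that budget).  From the final non-dominated front one plan is
selected by an explicit convention: minimal MA deviation, ties broken by TS
deviation then plate gap.  The plate model is an abstract rigid 60×16 mm
rectangular footprint sampled at 28 points — no vendor geometry.

## Numerical / degenerate-input choices

Probability clipping 1e−7 in all log terms; empty projections return zero
images rather than dividing by zero; two empty volumes score Dice 1; a
missing landmark propagates as a sentinel and is excluded (with a warning)
from error summaries; near-parallel triangulation rays raise a geometry
error (impossible at the fixed 90° view separation); voxelization raises a
sizing error if a landmark would leave the grid.  Training, cohort
generation, augmentation and the GA all draw from explicit
`numpy.random.default_rng` seeds; the pipeline derives per-stage seeds by
hashing the global seed, and repeated runs are bit-reproducible in
single-threaded execution.

## Problem sizes

The test suite and acceptance script use: 2 mm voxel phantoms for
measurement checks, a 40-phantom desk cohort (128 px / 32³, one augmented
acquisition per patient) for the learning experiment, 175 phantoms at
coarse spacing for dataset-assembly counting, 1000-point triangulation
round trips, and GA budgets around 32×25.  These sizes are the package's
desk-scale study conditions; the `full` preset preserves the full-scale
configuration (175 patients × 3 augmentations, 512 px / 128³, the reference
epochs) as configuration.

## Known limitations

Phantom realism as above; no scatter/beam-hardening/noise or detector
physics in the DRRs; no domain adaptation toward real radiographs; TS
accuracy is limited by plateau-plane fitting (the flagged residual is the
honest uncertainty signal); the separation ablation at desk scale measures
information content via oracle-separated inputs, not the trained separation
net's output quality; medial/lateral plateau slopes are not measured
separately; screw trajectories and vendor plate geometry are out of scope.
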