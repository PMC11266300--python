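# Methods

This note documents the models, numerical choices and known limitations of
the `ossa` pipeline in enough detail to reproduce or audit any stage.

## Segmentation (`ossa.volume`)

A scalar CT-like volume (anisotropic spacing in mm, arbitrary intensity
units) is binarized at an **inclusive** threshold of 350 — the comparison
direction is a convention choice; inclusive matches common segmentation
tools and makes thresholding monotone (raising the threshold never adds
foreground). Morphological closing uses a ball structuring element whose
**diameter** is the stated kernel size (3.0 mm default, radius 1.5 mm);
the diameter reading matches the referenced tooling convention, and a
radius override is exposed because the convention is genuinely ambiguous.
The element is built per-axis in voxel units from the spacing, so
anisotropic grids close isotropically in physical space. The grid is padded
before closing so structures at the boundary are not clipped.

Surface extraction is marching cubes at iso-level 0.5 on the binary grid
(padded by one voxel so foreground touching the boundary still closes),
with a mild Gaussian pre-smoothing of σ = 0.5 voxel. The smoothing exists
for a measured reason: iso-surfacing a hard 0/1 grid produces a staircase
surface whose area overestimates a smooth sphere's by ≈ 9% even though the
enclosed volume is within 1%; at σ = 0.5 the area error drops below 4%
while the worst surface displacement stays under half a voxel. Output
orientation is forced outward (positive enclosed volume).

## Remeshing (`ossa.remesh`)

Incremental isotropic remeshing with the standard four-step iteration:
split edges longer than 4/3·target, collapse edges shorter than
4/5·target, flip interior edges toward the regular valence (6 interior, 4
boundary), tangentially relax and re-project every vertex onto the
original surface. Five iterations by default. Implementation details that
matter:

* splits are *conforming* (midpoints shared through an edge registry), so
  no T-junctions are ever created;
* collapses respect the link condition and never merge a boundary vertex
  with an interior one, so closed surfaces stay closed and cut boundaries
  are refined but not eroded;
* re-projection uses an exact point-to-triangle closest-point kernel with
  k-nearest-vertex candidate pruning.

Measured on a radius-10 mm sphere at a 2 mm target: median edge 2.04 mm,
edge-length coefficient of variation 0.11, area within 1%, enclosed volume
within 1.6%, maximum deviation from the source surface < 0.5 mm.

## Anatomical frames and cuts (`ossa.anatomy`, `ossa.pipeline.align_bone`)

Condyle spheres are fit to expert-annotated vertex patches by the
linearized algebraic least-squares solve (exact on noiseless data; an
optional Levenberg–Marquardt geometric polish is available and agrees with
an independent nonlinear solver to 1e-6 on noisy data). The anatomical
(shaft) axis is the total-least-squares line through cross-section
centroids sampled over the middle 50% of the bone's dominant extent — the
construction is not dictated by any single convention, and both the
fraction and section count are parameters. The femoral frame keeps Y (the
shaft axis) exact and orthogonalizes the latero-medial direction against
it, on the argument that the anatomical axis is the privileged measurement;
X = Y × Z completes a right-handed triad. Because +Z always points toward
the *medial* condyle, the X direction (cranial/caudal) flips between left
and right bones; frames are right-handed either way, and sides are
modelled as separate populations (no mirroring by default).

Partial models: the distal femur (condyles) and proximal femur (head)
retain twice the reference-sphere diameter along Y from the respective
bone end; the proximal tibia is cut at the most distal point of the tibial
tuberosity (a manual landmark). Cuts are pure vertex-subset operations
with the open boundary left as-is. The proximal head segment is
re-origined at its head-sphere center after cutting: in the condyle-origin
frame, heads of bones of different lengths sit tens of mm apart, which
would make cross-size correspondence meaningless. The tibia frame uses the
shaft axis plus the tuberosity landmark for the cranial direction; the
patella (no shaft, no landmarks) uses principal axes with third-moment
sign fixing.

Regional rigid realignment (used to localize bending deformity, e.g.
whether Mode-2 curvature lives in the shaft or the condyles) is a
closest-point ICP: nearest-target-vertex matching, Kabsch solve, identity
initialization, convergence at 1e-8 RMS change or 50 iterations, no
scaling. It recovers a known 5° rotation to < 0.1°.

## Correspondence (`ossa.correspondence`)

The template is the specimen of **median centroid size** (RMS vertex
distance to the centroid; lower median for even K), remeshed to the 2 mm
target. "Median bone model" admits several readings; centroid size is the
natural order statistic in populations whose dominant factor is scale.
Every training surface — including the template's own source — is then
resampled onto the template connectivity by nearest neighbor: nearest
target *vertex* by default (ties to the lowest index), or nearest point on
the target *surface*. No non-rigid warping is applied; correspondence
quality therefore rests entirely on the anatomical pre-alignment, and the
per-shape mean nearest-neighbor distance is logged as a QC metric.

**Measured limitation.** Closest-point matching only sees the normal
component of inter-shape motion; tangential sliding is invisible, and the
bone end far from the frame origin sweeps past the template when sizes
differ. On a population with log-scale SD 0.1 (±20% size at 2 SD) this
distorts the recovered shape trajectory: the ground-truth-correspondence
model puts 97.5% of variance in Mode 1, while the same population pushed
through nearest-neighbor resampling yields ~78% (vertex) / ~82% (surface),
with the remainder leaking into ghost modes and the varus factor displaced
from Mode 2 to Mode 3 (`analysis/04_factor_recovery.py` quantifies this
side by side). A real study population with a comparable size range is
subject to the same effect, which is worth keeping in mind when
interpreting published per-mode percentages; fixing it properly requires
group-wise or non-rigid correspondence, which is out of scope here.

## The shape model (`ossa.ssm`)

PCA is computed through the thin SVD of the centered K×3P data matrix
(K ≪ 3P makes forming the covariance wasteful); eigenvalues are squared
singular values over (K−1), and all K−1 modes are kept, zeros included.
The SVD route is verified against an independent covariance
eigendecomposition to 1e-8 on randomized sets. Mode signs are fixed by
making each mode's largest-magnitude component positive (PCA signs are
arbitrary). Projection returns per-mode coefficients in SD units and is
exactly invertible on the training set. Variance tables report 3
significant figures. An all-zero spectrum (identical shapes) is a
reportable error, not a NaN.

## Synthetic populations (`ossa.synthetic`)

A canonical bone is the smooth union (polynomial smooth-min, k = 5 mm) of
implicit primitives — capsule shaft, condylar spheres, neck + head sphere,
trochanter bump for the femur; shaft + plateau ellipsoid + tuberosity for
the tibia; ellipsoid + apex + ridge for the patella — extracted by
marching cubes at 1.6 mm pitch. Prominences are deliberately gentle:
exaggerated pasted-on bulges caused correspondence attractor-jumping that
real, smoothly flaring cortical surfaces do not exhibit. Each specimen is
a smooth warp of the canonical mesh, applied in the fixed order
**condyle width → scale → varus → procurvation → torsion**:

| factor | default SD | units | implementation |
|---|---|---|---|
| log scale | 0.10 | — | global `exp(s)` multiply |
| varus/valgus | 2.0 | deg | graded rotation about X, distal half |
| procurvation | 1.0 | deg | graded rotation about Z, distal half |
| torsion | 1.0 | deg | graded rotation about Y, distal half |
| condyle width | 0.02 | fraction | z-scaling ramped over the distal third |

The scale SD of 0.1 makes size dominate, as it does across a mixed-breed
dog population; bend SDs of 1–2° sit inside the few-degree variation
reported for normal femora. Warps are smooth bijections, so watertightness
and the shared canonical connectivity are preserved exactly — the
generator is therefore its own correspondence oracle, and latent records
per specimen make factor recovery checkable. Landmark patches (condyle /
head vertex sets) are defined once on the canonical mesh by proximity to
the generating primitives and carried through warps by index.

Named group fixtures reproduce the study-style composition (whole-set
femur n=61 split 21/18/22 across size bands; 0–10 kg n=21; 10–25 kg n=18;
>25 kg n=22; chondrodystrophic n=18; retrievers n=13; tibia n=30; tibia
plateau n=72; patella n=85). The weight-band → base-dimension mapping
(120/160/200 mm shaft lengths) is a fixture convention, not biology.

Voxelization assigns 1000 inside / 0 outside (so the 350 threshold is
meaningful) by ray-crossing parity with a uniform-grid candidate filter
and a deterministic sub-micron jitter against edge-grazing degeneracies;
it agrees with an independent signed-distance oracle on >99.5% of voxels
away from the surface shell.

**What the generator does not emulate:** segmentation noise, cortical
texture, breed-specific local morphology, and scanner artifacts. Passing
the recovery tests demonstrates the pipeline's mechanics — alignment
covariance, correspondence behavior, PCA correctness — not clinical
fidelity.

## Validation design

Factor-recovery checks (Mode 1 = scale with > 90% of variance and
|corr| > 0.95 against log scale; Mode 2 = varus with |corr| > 0.9) are
evaluated on the generator's ground-truth correspondence, where the claims
are properties of the alignment + PCA machinery rather than of the
nearest-neighbor approximation; the NN-route numbers are reported
alongside, not substituted. Published-table consistency is checked to one
unit in the last printed digit — the printed per-mode values are
themselves rounded, so 27 of 110 cumulative cells differ by exactly 0.1
from a recomputation off the printed column, and a tighter bound is not
attainable from the published precision.

Problem sizes in the shipped analysis (n ≤ 85 specimens, 1.6–2.5 mm mesh
resolutions, ≤ 4300 vertices per specimen) were chosen so the full
analysis and test suite run in minutes on a single CPU while keeping every
population at its study-condition size.

## Known limitations

* Pure nearest-neighbor correspondence degrades under large scale spread
  (quantified above); no group-wise or non-rigid registration is offered.
* Landmark patches are inputs; nothing is auto-detected.
* The anatomical-axis construction assumes a dominant elongation
  direction and fails loudly on compact bones (the patella path uses
  principal axes instead).
* Remeshing assumes edge-manifold input and repairs nothing; defects are
  reported, not fixed.
* Statistical comparison *between* groups is out of scope; the package
  stops at per-group models, tables and mode meshes.
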