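# Methods

`doseaccum` implements an automated daily dose-accumulation chain for
MR-guided online adaptive radiotherapy (MRgART) of the prostate, together
with the synthetic data needed to validate it end to end. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## The workflow

For each treatment fraction the pipeline executes, in order:

1. **Focus box** — the PTV_eval bounding box expanded by 30 mm
   right-left and anterior-posterior and 20 mm superior-inferior, clipped
   to the image. All registration cost terms are evaluated only inside
   this box (the "ring" region that prioritizes the target and nearby
   organs at risk).
2. **Rigid registration** — maximizes normalized cross-correlation (NCC)
   between the planning image and the daily image over the focus box.
3. **Hybrid deformable registration** — a multiresolution cubic B-spline
   free-form deformation minimizing
   `w_I·SSD(intensity) + w_C·Σ_s SSD(SDM_s) + λ·bending`,
   where `SDM_s` is the truncated signed Euclidean distance map of
   structure *s*. Combining an intensity term with a contour-surface term
   is what makes the registration "hybrid".
4. **Dose warping** — the per-fraction delivered dose (on the daily grid)
   is pulled back to the planning grid by trilinear interpolation at
   `p + u(p)`.
5. **Progressive composite** — after *k* of *N* fractions,
   `composite = Σ_{i≤k} delivered_i(warped) + (N−k)/N · planned_total`,
   so delivered fractions successively replace the planned dose.
6. **Constraint evaluation and trigger** — the composite is scored against
   the institutional DVH template; a replanning flag trips when any
   constraint deviates *strictly more than* ±3% into violation.

### Conventions

* Grids are axis-aligned; array axes are (x, y, z) = (RL, AP, SI); the
  world coordinate of voxel *i* is `origin + i·spacing` (voxel-center,
  0-based, millimeters).
* Displacement fields use the pull-back convention: a planning point `p`
  corresponds to daily point `p + u(p)`. Warping daily data to the
  planning frame therefore needs no field inversion.
* Dose warping is plain dose mapping: no Jacobian energy/mass correction.
  This matches common commercial DIR-based accumulation. Under strongly
  compressive fields mapped dose is not energy-conserving; the coverage
  fraction (planning voxels mapping inside the daily support) is reported
  with every warp.

## Registration details

**Rigid.** Parameters are three Euler angles about the box center plus a
translation. The NCC metric is sampled on the box voxels (stride-2 scan,
then full-resolution refinement). The optimizer is multi-start Powell:
NCC under trilinear resampling is piecewise smooth but its numerical
gradients are noisy, so a derivative-free direction-set method is more
robust than gradient descent at equal cost. Results below 0.01 mm /
1e-5 rad snap to the exact identity so that self-registration leaves
downstream warps bit-exact.

**Deformable.** The field is a sum over pyramid levels of tensor-product
cubic B-splines. Defaults: three levels with fixed-image sampling strides
(4, 2, 1), control-point spacing 20 mm × stride, iteration caps
(60, 40, 30). Each level optimizes a *correction* on top of the rigid
initialization and coarser levels, with L-BFGS-B and an analytic gradient
(the adjoint of the separable B-spline interpolation). Data terms are
normalized to unit initial magnitude per family (intensity, contours), so
`w_I = w_C = 1` is scale-free. The bending surrogate is the mean squared
second difference of the control lattice over all axes and components —
mesh-size independent — with `λ = 2.0` chosen on the 64³ phantom recovery
experiment as the knee below which ground-truth recovery stops improving
while the field stays smooth. Truncating SDMs at ±20 mm keeps the contour
term local to each surface. Convergence: relative cost change below
`1e-5` or the iteration cap; a cost increase over a level raises an error
with diagnostics. Everything is deterministic; the accepted-iterate cost
trace is returned and is non-increasing within each level.

The `WorkflowConfig.fast()` preset (two coarse levels, 25 mm knots,
(15, 10) iterations, contour term on PTV_eval/rectum/bladder only, no
per-fraction gamma) is the batch profile used for cohort-style runs; the
problem sizes used in the shipped experiments are 64³ (3 mm) for
registration studies, 96³ (2 mm) for cohort emulation and 128³ (1.5 mm)
for the default planning phantom.

## DVH engine

Cumulative ≥-dose histograms with uniform 0.01 Gy bins on binary masks
(no partial-volume weighting — a documented dialect choice matching
mask-based pipelines). `Dx%` / `Dx cc` interpolate linearly between bin
edges, giving sub-bin accuracy without per-voxel sorting; the explicit
sorting computation is retained as a test oracle. The institutional
template ships as `DEFAULT_CONSTRAINTS` (five PTV_eval rows, five rectum
rows, bladder, urethra PRV, femoral heads, penile bulb). The femoral-head
row is applied to each femur individually. The ±3% replanning rule is
evaluated on each constraint's native reported quantity (the volume axis
for V-type rows), signed toward the violating direction, with a strict
inequality at the tolerance.

## Validation metrics

* **Geometric indices** — DICE, Jaccard, and Hausdorff distances between
  face-connected boundary voxels via Euclidean distance transforms.
  "HD mean" is the mean symmetric surface distance; a percentile-HD
  variant is available (`hd_percentile`). Distances are voxelized-surface
  distances, not mesh distances.
* **Gamma analysis** — global 3D gamma, defaults 3% / 3 mm with a 10%
  low-dose threshold, dose criterion as a percentage of the prescription.
  The offset search covers a 3×DTA radius on a half-voxel sub-lattice,
  visits candidates in increasing distance and prunes voxels whose best
  gamma already beats the remaining distance term, so agreeing
  distributions cost almost nothing.
* **t-test** — Welch by default (pooled optional); two zero-variance
  samples with equal means return p = 1.

## The synthetic phantom

The generator emulates the study conditions of a 0.35 T MR-linac prostate
SBRT program: ~1.5 mm isotropic volumetric imaging (the default 128³ grid
covers a 19.2 cm pelvis window), a 36.25 Gy / 5-fraction prescription
normalized so PTV_eval D95% equals the prescription exactly, and a
PTV_eval around 69 cc — inside the reported clinical size range.
Anatomy is geometric: prostate/PTV ellipsoid, urethra (interior to the
prostate) with a 3 mm PRV expansion, rectal tube, bladder ellipsoid,
femoral-head spheres, penile bulb. PTV_eval is the PTV minus every OAR by
construction. Intensities are piecewise constant per organ plus Gaussian
noise (default sd 4 on a ~100–220 unit scale); there is no bias field, no
MR physics, and no intrafraction motion.

Inter-fractional change is a sum of three analytically known displacement
components: radial bladder filling, an anterior Gaussian rectal-distension
bump (σ = 20 mm), and a band-limited random field (white noise smoothed at
the correlation length, rescaled to the requested peak). Defaults
(bladder scale 1.05, bump 4 mm, random 3 mm at 40 mm correlation) produce
organ volume changes of a few percent — plausible day-to-day pelvic
variation. Each component's peak must stay below 0.45× its correlation
scale, which empirically guarantees a positive Jacobian determinant (also
checked numerically at every voxel). Daily images are produced by pushing
the planning image through the truth field (via a fixed-point numerical
inverse), and the daily delivered dose is *re-planned* on the deformed
anatomy — mimicking online adaptation — then scaled to one fraction.

Because daily contours are truth-warped planning contours, registration
experiments measure pure algorithmic recovery with no observer noise; an
optional contour-jitter is deliberately absent so ground truth stays
exact. Consequently, passing recovery tests (PTV DICE ≥ 0.95, MSD ≤ 1
voxel under ≤ 8 mm smooth fields) demonstrates correctness of the
machinery under known smooth deformations — not clinical registration
accuracy on real MR contrast, sliding interfaces, or large rectal gas
changes.

## Degenerate inputs and tie-breaks

Empty masks raise naming the structure; oblique NIfTI/DICOM orientations
raise rather than resample silently; out-of-support samples are 0 for
images/doses and handled with clamped edges for SDMs; mask warps
threshold the interpolated indicator at 0.5; RT-structure rasterization
uses voxel-center-in-polygon with even-odd (XOR) combination across
contours of a slice. Identity fields short-circuit to bit-exact copies.

## Known limitations

No Jacobian-weighted (energy/mass conserving) accumulation; no
biologically weighted (EQD2/BED) summation; no oblique or non-isotropic
clinical grids beyond axis-aligned support; the "manual" workflow in
comparisons is any externally supplied field/dose pair — interactive
landmark editing has no algorithmic counterpart here; gamma criteria and
DIR hyperparameters are configurable but their clinical defaults are
conventions, not fitted values.
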