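# Methods

`athero3d` quantifies atherosclerotic plaque burden and composition in
light-sheet fluorescence microscopy (LSFM) stacks of whole mouse aortas.
The workflow has five computational stages, each exposed as a library
module and exercised end to end on synthetic phantoms:

1. **Plaque segmentation** (`plaque_unet`): a 2D U-net segments plaque on
   each autofluorescence cross-section; slice masks are restacked into a 3D
   plaque volume.
2. **Anatomy labelling** (`atlas_reg`, `anatomy_unet`): the aorta is
   partitioned into descending aorta (DESC), aortic arch (ARCH),
   brachiocephalic artery (BCA), left subclavian artery (LSA) and left
   common carotid artery (LCCA), either by multi-atlas registration or by a
   3D U-net.
3. **Volumetry** (`quantify`): plaque voxels are grouped into connected
   objects, converted to mm³ via the voxel volume, and attributed to
   compartments.
4. **Composition** (`quantify`): CD45 (pan-leukocyte) signal is thresholded
   *inside plaque only* and reported per object and per compartment.
5. **Statistics** (`stats`): rank-based group contrasts with
   Benjamini–Hochberg FDR control.

## The segmentation model and its loss

Both U-nets are classic encoder–decoder networks with skip connections:
two 3×3(×3) convolutions with ReLU per level, 2× max-pooling down,
nearest-neighbour upsampling and skip concatenation up, a 1×1 head, and
sigmoid (2D, one class) or softmax (3D, six channels) outputs.  The 3D net
additionally uses InstanceNorm (per-sample, per-channel, deterministic)
after each convolution: without any normalization, tiny volumetric nets
train erratically, with entire compartments collapsing depending on the
initialization seed.  Depth and filter counts are configurable; all
reference runs use tiny instances (depth 2, 8 base filters).

Training minimises one minus the smoothed dice coefficient

    d = (2·Σ(x·y) + 1) / (Σx + Σy + 1)

computed per image and averaged over the batch, where `x` is the predicted
probability map and `y` the binary target.  The +1 smoothing keeps the loss
defined (and equal to 0) on slices without plaque.  The 3D variant averages
the smoothed dice per class; by default the unlabelled channel is included
in that average (``loss_includes_background``).  Excluding it — averaging
over the five labelled compartments only — leaves the background entirely
unsupervised, and the argmax decode is then free to spray whichever class
the optimizer favours across empty space; masking predictions to the aorta
removes most of the spray but not the part inside the vessel.  Evaluation,
in contrast, always scores only the five labelled compartments, with
unsmoothed per-class overlap; a class absent from both prediction and
truth scores 1 by convention.

Optimisation is Adam (lr 1e-4 for 2D training and fine-tuning, configurable
for 3D — see scaling below) with early stopping on validation dice and
restoration of the best-validation weights.  Everything is seeded: equal
seeds give bit-identical histories on one CPU thread.

The networks, losses and optimizer are implemented in a small numpy engine
(`nn.py`): channels-last layout, convolutions evaluated as one GEMM per
kernel offset, exact argmax bookkeeping in pooling.  Its gradients are
verified against numerical directional derivatives in the test suite.

## 2D preprocessing

Slices are resized to the network input (bilinear, anti-aliased on
downscale; aspect ratio is stretched, not padded) and normalised by CLAHE
(clip limit 0.01, 8×8 tile grid; both configurable).  A constant slice is
mapped to zero — there is no contrast to equalize, and this makes the
operation idempotent on constants.  The full-scale input default is
608×480 px.

## 3D preprocessing and atlas registration

For anatomy labelling the autofluorescence volume is binarized (Otsu by
default; a fixed threshold is configurable), the lumen is closed with a 3D
hole fill, the filled binary is resampled to the registration grid
(full-scale default 300×260×190), and each foreground voxel is encoded by
its Euclidean distance in µm to the nearest background voxel.  Physical
rather than voxel units are used because samples differ in spacing.  The
distance encoding converts the thin-walled tube into a smooth solid ramp,
giving the mean-squared-error metric useful gradients everywhere inside
the vessel.

Registration runs rigid → affine → b-spline per atlas.  Numerical choices:

* multi-resolution pyramid with shrink factors (8, 4, 2) — the optimizer
  never works at full resolution; smoothing sigmas (2, 1, 0) voxels;
* seeded random metric sampling (10% default) — deterministic and an order
  of magnitude cheaper than dense evaluation;
* regular-step gradient descent with physical-shift scale estimation for
  the rigid and affine stages; LBFGS for the b-spline stage, where scale
  estimation over thousands of control-point parameters would dominate
  runtime;
* b-spline mesh: 8 control points along the longest axis, scaled
  isotropically.

The best atlas is the one whose warped binary maximises plain dice against
the sample binary, computed after the b-spline stage; ties break toward the
lowest atlas id.  Failed optimizations are returned flagged, not raised,
and excluded from selection.

Label post-processing enforces an exact partition of the sample's aorta
mask: 3D per-class hole filling, removal of labels outside the mask, then
nearest-labelled-voxel assignment (Euclidean, physical units) for uncovered
aorta voxels.  The same routine serves the 3D U-net route after
nearest-neighbour upscaling of the 64³ (desk scale: 16³) prediction.
Argmax decoding makes overlapping class predictions impossible; the
nearest-neighbour rule still applies to voxels no class claims after
masking.

## Volumetry and CD45 composition

Volume is voxel count × voxel volume (µm³) × 1e-9 mm³/µm³ — never an
interpolated surface.  Individual plaques are 3D connected components
(26-connectivity by default, 6 configurable); an object's compartment is
the majority anatomy label over its voxels, ties toward the lowest class
id.  Sparse manual-annotation volumes use the slab rule: annotated area ×
(stride × z-spacing); with every 5th slice at 8 µm steps each annotation
stands for a 40 µm slab.  With stride 1 the estimate equals the full-mask
volume exactly.

CD45 positivity has no universal threshold, so the default is Otsu computed
over plaque voxels only (a fixed threshold is configurable), and CD45 is
never quantified outside plaque — the measurement is immune-cell
infiltration *of plaque*, not vessel-wall residency.

## Statistics

All inference is rank-based because plaque volumes are strongly
right-skewed in low-plaque groups.  Two-sided throughout.  The
Mann-Whitney U test compares independent groups (exact enumeration up to a
combined n of 25 without ties, tie-corrected normal approximation
otherwise).  The paired compartment contrasts use the Wilcoxon signed-rank
test on within-animal differences — the standard paired nonparametric
procedure — with zero differences dropped.  Spearman's r_s is Pearson
correlation on average ranks.  Benjamini–Hochberg adjustment is applied
within each contrast family (compartment contrasts; per-compartment CD45
diet contrasts); significance is called at 0.05 on adjusted values where
FDR applies.  Note that BH-adjusted values are *not* idempotent in
general; the suite asserts monotonicity and order preservation instead.

## The phantom generator

Phantoms emulate the specimen the pipeline targets: a thoracic aorta with
arch and the three large branch arteries, dissected ~3–4 mm into the
branches, imaged as a 16-bit z-stack at anisotropic spacing (default
8 × 4.8 × 4.8 µm in Z, Y, X).

Geometry: the centerline is a straight descending segment, a half-torus
arch, a short unlabelled ascending stub and three straight branches whose
origins span the upper arch at 45°/90°/135° — in the mouse the BCA and LSA
roots sit roughly an arch radius apart, and this spread also keeps the
three origins resolvable at coarse network grids.  Tubes have constant
radius per segment (aorta 40 µm, branches 20 µm at desk scale — a
uniformly miniaturised vessel, about an order of magnitude below real
murine calibre, chosen so whole cohorts fit in test-suite minutes), with a
lumen at 55% of the outer radius.  Plaques are wall-attached ellipsoids
(semi-axes jittered ±25%) placed without contact so that the per-object
ground-truth table matches connected-component analysis exactly; placement
is weighted toward the arch and BCA, where murine plaque burden
concentrates.  Intensities are constant per tissue class (background 1000,
lumen 4000, wall 20000, plaque 32000, CD45 28000 on the 16-bit scale) plus
additive Gaussian noise (sd 600), clipped to [0, 65535].

The CD45 channel implements the maturation gradient: objects with
equivalent-sphere radius below 25 µm are stained throughout; larger ones
only within a 12 µm rim of their surface, mirroring leukocyte restriction
to the periphery of advanced plaques.

What the phantoms deliberately do **not** model: light-sheet optics (PSF,
attenuation, stripe/tiling artefacts), vessel-wall histology, anatomical
variation of the centerline beyond arch-curvature and radius scaling, and
intensity texture within tissue classes.  Passing the phantom experiments
therefore demonstrates that the *pipeline machinery* — preprocessing,
training dynamics, registration, volumetry, statistics — is correct and
internally consistent; it does not certify performance on real microscopy,
where contrast is subtler and anatomy more variable.

## Desk-scale study conditions

The reference experiments (test suite and `scripts/acceptance.py`) run the
full workflow at sizes one CPU core completes in minutes.  These sizes are
the package's documented study conditions:

| experiment | condition |
|---|---|
| 2D training corpus | 4 phantoms × every 4th slice = 64 annotated slices (48/12/4 train/val/test), native 72×72 grid |
| 2D plaque radii | 20–45 µm, ≥ 4 px at the desk grid (the full-scale default 12–40 µm includes sub-voxel objects that are unresolvable here) |
| 2D schedule | ≤ 200 epochs, patience 50, batch 2, no augmentation |
| fine-tuning domain shift | 1.5 px in-plane optical blur, compressed contrast, 0.55–1.35× one-sided illumination gradient, noise sd 1200 (a pure intensity change is normalised away by CLAHE; contrast inversion is unlearnable inside a short fine-tune) |
| subsample study | pool of 100 shifted slices drawn from four phantoms; sizes 25/50/100 × 3 seeded repeats, 15 epochs each (a pool from fewer specimens makes large subsets overfit them and inverts the trend) |
| registration | grid 150×130×95, 8 atlases (arch curvature 0.9–1.1×, radius 36–44 µm), iterations 60/30/15, 2% sampling |
| 3D anatomy | 12 phantoms, 4 leave-two-out folds, 16³ input, 8 base filters, lr 1e-3, 80 epochs without early stopping (validation dice plateaus and then jumps late at this scale, so a finite patience freezes underfit weights) |

Two of these deliberately depart from the full-scale defaults and why:

* **3D learning rate.** The full-scale configuration (64³ inputs, hundreds
  of augmented volumes, 300 epochs) uses Adam at 1e-5.  At 16³ with tens of
  epochs that rate cannot converge; the desk runs use 1e-3.  Learning rate
  and schedule scale together.
* **Augmentation.** Skew/rotate/flip/zoom/elastic augmentation (30%
  probability each) is implemented and property-tested, and belongs in the
  full-scale 2D protocol; under the desk schedule it delays convergence
  past the epoch budget and is disabled in the reference experiment.

Known limitations: the CPU engine is practical only for tiny networks (the
608×480/depth-4 full-scale configuration would need hours per run); the
phantom cohort shares one centerline topology, so anatomy
cross-validation measures robustness to noise, plaque load and geometric
scaling rather than to true anatomical variability; and no claim is made
that desk-scale dice values transfer to real LSFM data.
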