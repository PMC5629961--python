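# Methods

This note documents the models, numerical choices and limitations of the
package in one place.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Color deconvolution follows the Ruifrok–Johnston optical-density model:
`OD = −log10(max(I, 0.5)/255)` per channel, and densities `D = OD · M⁻¹`
for a 3×3 stain matrix `M` with unit-norm rows.  The floor of 0.5 on the
transmitted intensity keeps the logarithm finite for black pixels and
bounds the round-trip error at one intensity level.  The default stain
vectors are the "H&E 2" preset of the Fiji/ImageJ colour-deconvolution
plugin (hematoxylin `[0.490, 0.769, 0.410]`, eosin `[0.046, 0.842,
0.537]`); the preset leaves the third (residual) vector zero and we
complete it with the unit vector orthogonal to the first two.  The matrix
is a configuration entry and can be replaced per run.  Only the
hematoxylin channel is kept (configurable index), re-expressed as a
transmitted intensity `255·10^(−d)` so that dense stain is dark.

CLAHE uses a 2.0 clip limit in the 256-bin histogram-clipping convention
(mapped to scikit-image's normalized `clip_limit = 2/256`) on an 8×8 tile
grid.  Both values are exposed in the run configuration; the qualitative
behavior (contrast widening on low-contrast input, identity on constant
input) is what the tests pin down, not specific values.

The resolution policy is: classify at half resolution, segment at full
resolution.  Downsampling of intensity and probability rasters uses
local-mean (area) averaging, upsampling is bilinear; label rasters always
use nearest-neighbor so the label alphabet is preserved.  Output
dimensions are `floor(dim × factor)` — a 775×522 raster becomes 387×261 at
factor 0.5.

## Training data

The four-class transform maps background/gland to C₀/C₁ on benign images
and C₂/C₃ on malignant ones, so a single four-class classifier carries
both the figure-ground and the benign/malignant signal.  Separator ground
truth is rasterized from polyline annotations (discrete line segments
dilated to a 3-px default thickness).

Patch sampling is class-balanced: centers drawn uniformly without
replacement from each class's eligible pixels (with-replacement fallback
plus a logged warning when a class is under-represented, which routinely
happens for the thin separator class).  Patches whose window crosses the
border are completed by mirror padding; this preserves local texture
statistics better than zero padding and avoids dataset-specific stitching.
The default of 125,000 patches per class matches the full-scale training
regime; the tests and the acceptance script use a few tens per class.
Rotation augmentation produces `count` copies at multiples of 36° with
bilinear interpolation and mirror boundary; the label is taken from the
unrotated center.

## Networks

Both classifiers are LeNet-style stacks of K = 7 weighted layers — four
valid (unpadded) convolutions with ReLU, 2×2/stride-2 max-pooling after
the first three, then three fully connected layers and a softmax:

* Object-Net: conv 80@11², 96@7², 128@5², 160@3²; FC 1024, 512, 4.
* Separator-Net: conv 64@9², 96@7², 128@5², 160@3²; FC 1024, 512, 2.

On a 101×101 patch the object variant's spatial sizes are
101→91→45→39→19→15→7→5 (valid convolution shrinks by `kernel−1`; pooling
halves with floor).  The pooling placement of the Separator-Net mirrors
the Object-Net (after convolutions 1–3); its per-layer pooling is not
independently constrained, so this symmetry is an explicit assumption.

The engine is a small numpy CNN (im2col + BLAS matrix products, manual
backprop, float32).  Weight initialization is the variance-preserving
scaled-uniform fan-in scheme (`U(−√(3/fan_in), √(3/fan_in))`), seeded, so
two builds from the same seed are bit-identical.  The first convolution
does not backpropagate to its input.  Dropout (default rate 0.5) applies
to the input of the second and third fully connected layers.

Optimization is minibatch SGD with classical momentum and weight decay
0.005 on weights (not biases).  The learning rate starts at η₀ = 0.0025
and decays linearly to 0.2·η₀ over 100 epochs; momentum rises linearly
from 0.8 to 0.99 over 50 epochs.  Training stops when the validation
error has not improved for 20 epochs (configurable), or immediately when
it reaches zero — a zero error cannot improve further, so waiting out the
patience window would only burn compute.  Parameters from the
best-validation epoch are returned, along with a per-epoch history of
loss, training error (on a capped subset) and validation error.

Mini-batches are internally split into memory-bounded micro-batches whose
gradients are accumulated before a single update, so the update rule is
independent of the micro-batch size.  Inference slides the 101×101 window
at stride 1 with mirror padding; for stride > 1 the coarse grid is
bilinearly interpolated and renormalized.  Softmax outputs are computed in
float64 so per-pixel distributions sum to 1 within 1e−5.

## Refinement and segmentation

Figure/ground fusion is `p_fg = max{(I_C1+I_C3) − S, 0}`,
`p_bg = min{(I_C0+I_C2) + S, 1}`, computed at the classifier scale and
bilinearly upsampled to full resolution before the data term is built;
running without a separator model sets S ≡ 0 (the ablation variant).

The segmentation energy is the weighted-TV relaxation of the geodesic
active contour model with a linear data term over the box [0,1].  The
edge function `g = exp(−α‖∇I‖^β)` (defaults α = 10, β = 0.95) is computed
on the CLAHE-preprocessed structure channel rescaled to [0,1], with
forward differences and replicate (Neumann) boundary.  Data weights are
the logit of the dominant class probability (probabilities clipped to
[1e−6, 1−1e−6]), negated for foreground, and zeroed wherever
`max(p_fg, p_bg) < τ` (default τ = 0.65) — below that confidence the
segmentation is driven by contour length alone.  λ defaults to 0.1.

**Discretization.**  The TV term is discretized with the anisotropic (ℓ1)
norm of the forward-difference gradient, `Σ g·(|∂x u| + |∂y u|)`.  The
anisotropic choice is deliberate: the discrete co-area identity holds
exactly for it, so thresholding the relaxed global minimizer at any level
yields a global minimizer of the corresponding binary discrete energy.
The test suite verifies this against exhaustive enumeration on random 4×4
and 5×5 problems (tolerance 1e−6).  A discrete isotropic norm would lose
the exact co-area property and with it the certificate.

**Solver.**  First-order primal–dual iteration with dual projection onto
`{|p_k| ≤ g}` componentwise, primal projection onto [0,1], extrapolation
θ = 1, and steps σ = τ_step = 1/√8, which satisfies the stability bound
for the discrete gradient (operator norm² ≤ 8).  Iterations stop when the
per-pixel primal–dual gap `(E(u) − D(p))/n` drops below `tol` (default
1e−6) — an optimality certificate — or at `max_iters` (default 2000), in
which case the last iterate is returned with a warning flag.  The primal
energy is traced per iteration; primal–dual methods are not strictly
monotone, so the trace is only tested for windowed-mean decrease.  The
field is initialized from the sign of the data term (1 where w < 0, 0
where w > 0, 0.5 where w = 0).

Post-processing thresholds u at 0.5, fills enclosed background holes
(8-connected background), removes components below 500 px (4-connected
foreground) and labels the survivors in raster order.  The synthetic-scene
tests use a smaller minimum area because their glands are smaller than
real ones at full resolution; the threshold is a parameter everywhere.

**Parameter tuning.**  `grid_search_tv` scans α ∈ [0.5, 15],
β ∈ [0.35, 0.95], λ ∈ [0.01, 10] and scores every grid point by the pixel
Dice of the thresholded solution against the binary gland mask.  Whether
"pixel-level Dice" means pooling all pixels or averaging per image is
ambiguous, so both the per-image mean and the micro-average are reported;
the argmax uses the per-image mean.  τ is tuned separately over
{0.5, 0.65, 0.8, 0.95}.

## Tissue classification

`P(benign)` and `P(malignant)` are the spatial means of (I_C0 + I_C1) and
(I_C2 + I_C3); the argmax is the decision and the winning mean its
confidence.  Exact ties resolve to benign and are logged — the direction
is arbitrary, determinism is the point.  The decision is taken from the
half-resolution maps; a spatial mean is unaffected by bilinear resampling
up to boundary effects.

## Evaluation metrics

A segmented object is associated with the ground-truth object it shares
the most pixels with.  The 50% rule is interpreted as intersection over
the *ground-truth object's* area; this reading guarantees that at most one
segmented object can claim a given ground-truth object (two fractions
> 50% of the same object cannot coexist), which keeps TP + FN equal to the
number of ground-truth objects.  Intersection-over-union is available
behind the `overlap="iou"` flag.  Precision, recall and F1 guard 0/0 to 0.

Object-level Dice is the average of two directed, area-weighted sums over
max-overlap partners; an instance with no overlapping partner contributes
Dice 0.  Object-level Hausdorff mirrors the same weighting with the plain
symmetric Hausdorff distance as the inner term (its printed definition is
self-referential, which we read as a typographical slip).  An instance
with no overlapping partner is scored against the instance on the other
side with the smallest Hausdorff distance — this keeps the aggregate
finite while penalizing spurious and missed objects; if one side has no
instances at all the value is undefined (NaN).  `Dice(∅, ∅) = 1` by
convention.  Distances are Euclidean in full-resolution pixel units.
Dataset-level numbers are reported as mean (SD) over individual images.

Benign/malignant classification metrics come from a 2×2 confusion matrix
(rows = predicted, columns = ground truth): accuracy is trace/total, and
per-class precision/recall/F1 treat each class in turn as positive.  Note
one published table cell for this family of metrics (benign F1 on one
test set) is inconsistent with its own confusion matrix, which gives
≈0.985 rather than the printed 0.976; the package reports the recomputed
value.

## Synthetic scenes

The generator emulates the tissue components that drive the real problem:
glands as a bright lumen wrapped in a dark epithelial ring, on pink,
textured stroma.  Benign glands are smooth ellipses with concentric
lumina; malignant glands get low-order Fourier boundary perturbations
(non-convex outlines), shrunken/off-center or fully occluded lumina, and a
darker, more blue-purple epithelium (hyperchromatic nuclei), which makes
the four-class problem learnable at small scale.  Gland placement is
rejection sampling under a minimum boundary gap (default 12 px); a
configurable fraction of glands is placed as near-touching pairs (default
gap 3 px).  Separator ground truth is defined geometrically, since the
real criterion ("very close to two or more gland borders") is manual: the
stroma midline (|d_A − d_B| ≤ 1) between gland pairs whose boundary gap is
below 10 px, dilated to 3 px.  All randomness flows from a single seed;
identical configurations are bit-identical.

Simulated classifier outputs are blurred one-hot class maps with optional
uniform-replacement pixel noise, renormalized per pixel.  The
`bridge_radius` option morphologically closes the gland class across
narrow background corridors, reproducing the characteristic failure of a
real gland classifier on touching glands — the merge that separator
refinement is there to undo.  With bridging enabled, the ablation
(S ≡ 0) merges near-touching pairs and the separator-refined run splits
them; the tests assert the strict object-count difference.

**What passing synthetic tests does not show.**  The scenes have no
nuclear texture, no staining variability, no out-of-focus regions, no
"true" background (non-tissue), and their class-conditional color
distributions are far more separable than real H&E tissue.  Synthetic
end-to-end scores (detection F1 = 1.0, object Dice ≥ 0.95 on noise-free
scenes) validate the plumbing and the convex solver, not clinical
performance; published full-scale segmentation scores require the
original challenge dataset and full-scale training, which are outside
desk scale.

## Problem sizes used in tests and the acceptance script

Solver optimality is checked on ~100 random 4×4/5×5 grids (the 5×5
enumeration uses an exact meet-in-the-middle decomposition over column
blocks).  End-to-end runs use 192²–256² scenes with 5–6 glands.  The
training checks use the canonical 101×101 architectures on a separable
texture fixture — one sinusoidal grating orientation per class, random
phase per patch — with 30 training / 15 validation patches per class and
batch size 2.  Orientation classes are the right separable stimulus for a
convolutional classifier: flat intensity levels make every feature in the
positive ReLU cone collinear with the input mean, which leaves a long
symmetry-breaking plateau, whereas oriented textures give the first-layer
filters orthogonal signals and the loss descends monotonically from the
first epochs.  With so few patches, small batches are what give the
optimizer schedule enough updates per epoch to converge within the
50-epoch window.  The scene-trained pipeline test
uses a reduced-width replica of the same 4-conv/3-FC layout on 53×53
patches so that training and stride-1 inference stay in seconds-to-minutes
on one CPU.

## Known limitations

* The CNN engine is CPU-only and unoptimized relative to GPU frameworks;
  stride-1 inference over large images is the dominant cost.  The
  fully-convolutional inference rewrite (FC layers as 1×1 convolutions
  with dilation) is not implemented.
* Stain vectors are fixed per run; no data-driven stain estimation.
* Whole-slide (pyramidal) formats and tile stitching are out of scope;
  inputs are single rasters.
* The separator ground-truth rule on synthetic scenes is geometric and
  exact, unlike the manual annotations it stands in for.
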