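# Methods

This note records the models, conventions, numerical choices and known
limitations behind `inpaintseg`, at the level of detail a maintainer or
reviewer needs to judge what the package's tests do and do not establish.

## Corruption model

Both pretext tasks corrupt a normalized image with square `K x K` patches,
placed iteratively until the number of corrupted pixels equals or exceeds
1/4 of the image area.  The quarter-area rule makes the corruption level
independent of `K`, so inpainting difficulty varies only through patch
geometry.  Conventions:

- **Anchors** are `(row, col)` top-left corners, 0-based, with half-open
  patch extents `[r, r+K) x [c, c+K)`.
- **Stop rule**: the loop stops after the placement step (one patch for
  prediction, one pair for restoration) that first meets the target;
  partial patches are never used.  Hence the corrupted fraction always lies
  in `[1/4, 1/4 + s/(H*W))` where `s` is one step's pixel area (`K^2` or
  `2K^2`).
- **Random sampler**: anchors uniform over `[0, H-K] x [0, W-K]`; patches
  may overlap and coverage is counted as the union of patch pixels.  For
  restoration, the two anchors of a pair are redrawn until the pair itself
  is disjoint; different pairs may overlap each other.  Only the
  within-pair constraint is required for the swap to be well defined.
- **Poisson-disc sampler**: dart throwing with rejection at center distance
  `< K*sqrt(2)`.  `K*sqrt(2)` is the smallest Euclidean center-distance
  bound that guarantees two axis-aligned `K x K` patches cannot overlap
  (overlap requires `|dr| < K` and `|dc| < K`, hence distance `< K*sqrt(2)`).
  Dart throwing can jam below the required patch count at dense packings,
  so the sampler restarts from scratch (fresh sub-seed, up to 200 restarts,
  `max(20000, 300*n)` darts each) before raising.  The rejection core uses
  a uniform grid of cell size `K` (at most one accepted point per cell,
  5x5-cell neighborhood checks) and is numba-compiled; at 512x512 all
  `K in {8, 16, 32, 64}` configurations succeed in milliseconds.
  A Poisson-disc mask therefore consists of fully disjoint patches and, for
  `K = 64` at 512x512, of exactly 16 patches covering exactly 1/4 of the
  image.  Maximal (Bridson-style) sampling is deliberately not used: only
  the distance constraint matters and dart throwing is simpler at these
  densities.
- **Feasibility precondition**: the Poisson sampler requires
  `K <= min(H, W)/3` so that quarter-area coverage with disjoint patches is
  reliably placeable.
- **Mask banks**: 100 base masks per configuration (default), drawn once
  before training; each training draw picks a base mask and a quarter-turn
  rotation uniformly, giving 400 effective masks.  Rotations act on anchor
  coordinates (one CCW turn maps an anchor to `(W-c-K, r)`), so rotated
  masks keep all invariants; 90/270-degree turns require square images.
  Masks are image-independent geometry; one bank serves every image of a
  given shape, and multi-channel (CT) images reuse the same spatial mask on
  every channel so that no channel leaks uncorrupted information.
- **Application**: prediction zeroes masked pixels (images are normalized
  first, so zero is the image mean); restoration exchanges patch contents,
  preserving the exact pixel-value multiset of the image.
- The area target is exposed as `area_fraction` (default 1/4).

## Network

A standard 2D U-Net expressed as three disjoint parameter scopes:

- **encoder** — `depth` resolution levels of two (3x3 conv, GroupNorm,
  ReLU) blocks with 2x2 max-pooling between levels; channel widths
  `base_filters * 2^level`;
- **decoder** — per level a 2x2 stride-2 transposed convolution, skip
  concatenation with the encoder feature map of the same resolution, then
  two conv blocks (the first convolution after concatenation belongs to the
  decoder scope);
- **post_processing** — a final 1x1 convolution defining the head:
  `in_channels` outputs for inpainting, 4 for segmentation.

Weight standardization reparameterizes every 3x3 kernel to zero mean and
unit variance per output filter at use time, with gradients chained through
the map; epsilon `1e-7` in the denominator keeps standardized variances
within `1e-4` of one even for low-variance kernels while damping constant
kernels to zero.  The 1x1 head is a plain convolution (standardizing a
head's weights would constrain its outputs to zero-mean combinations).
GroupNorm uses 8 groups by default, eps `1e-5`; the group count must divide
`base_filters`.  Initialization is He fan-in normal, seeded; two models
built with the same config are bit-identical.

The layers, backward passes and the Adam optimizer (`beta1 = 0.99`,
`beta2 = 0.995`) are written directly in numpy.  Backward passes were
verified against float64 central finite differences (relative error
`< 3e-7` across all layer types and scopes).  Training runs in float32.

## Training

- **Pretraining** draws one fresh mask per image per optimization step and
  minimizes the mean squared error of the reconstruction against the
  uncorrupted original, over the full image (corrupted and uncorrupted
  regions alike).  MSE is the monotone per-pixel form of the Euclidean-norm
  objective and keeps magnitudes comparable across image sizes; the
  *evaluation* metric is the true L2 norm of the difference image
  (per channel, then averaged over channels, for CT).
- **Fine-tuning / supervised baseline** minimize soft Dice loss aggregated
  over mini-batches per class: intersections and denominators are pooled
  over all pixels of the whole batch before forming the per-class ratio,
  and the loss is one minus the mean over the 4 foreground classes.
  Labels include background (class 0) but no background Dice term; the
  segmentation head's 4-class softmax is discretized as argmax with a pixel
  assigned to background when no class probability exceeds 0.5
  (configurable threshold — the discretization rule is a package choice).
- **Early stopping** monitors a validation objective (reconstruction loss
  on a fixed set of corrupted validation images for pretraining; Dice loss
  for segmentation) with patience 10 and max 200 epochs by default, and
  always returns the weights of the best validation epoch, not the last.
  These early-stopping parameters are package defaults, not values taken
  from elsewhere; phantom-scale experiment plans override them downward.
- **Schedules**: `immediate` fine-tunes everything from the first step;
  `freeze_then_unfreeze` first trains with the transferred scopes frozen
  until early stop, then unfreezes all scopes and trains again with a fresh
  optimizer state, at `second_lr` if configured (e.g. 1e-3 then 1e-4) else
  the initial rate.  Frozen parameters are skipped entirely by the
  optimizer — weights and moment estimates stay bit-identical through a
  frozen phase.
- **Label subsets** are nested: ids are shuffled once under the seed and
  subsets are prefixes, so every member of a smaller subset belongs to all
  larger ones.  Sizes are `max(1, round-half-up(fraction * n))`; explicit
  `size_overrides` exist for reproducing externally fixed subset sizes
  whose rounding does not follow a single consistent rule.
- All stages are deterministic given their seeds (seeded mask draws, data
  order, initialization); identical seeds give loss histories identical to
  float32 round-off.

## Statistics

- **Power-law fit** `y = a*x^k + c`, `k > 0` so `x = 0` maps to the offset
  (the supervised baseline point); `x` is the pretraining-data amount in
  percent of the standard pretraining set.  Nonlinear least squares
  (`scipy.optimize.least_squares`) restarted from exponents
  {0.1, 0.3, 0.5, 0.7, 1.0} with `k` bounded in `[1e-8, 5]`; best solution
  kept.  Three-parameter fits to a handful of points are
  initialization-sensitive, hence the multi-start.  The residual standard
  error is reported with the `n - 2` denominator.  At least 4 distinct x
  values are required when all three parameters are free.
- **Wilcoxon signed-rank (one-sided)**: zero differences dropped, midranks
  for ties.  For `n <= 12` remaining pairs the null tail probability is
  computed by exact enumeration of all `2^n` sign assignments over the
  observed ranks (valid under ties); for larger `n` a normal approximation
  with tie-corrected variance and no continuity correction is used, which
  matches scipy's uncorrected approximate method.  At least 5 nonzero
  differences are required.
- **Strategy ranking**: per dataset, paired per-image class-averaged Dice
  scores are pooled across the label-limited regimes into a single test per
  strategy (pooling is the default; per-regime testing is possible by
  filtering the input table).  Strategies are sorted by ascending p-value;
  the selected strategy is the one present in every dataset's top 3 (ties
  broken by mean rank), and an empty intersection is reported explicitly as
  "no consensus".  No multiple-testing adjustment is applied across the
  strategy grid — the ranking is a heuristic on raw p-values.

## Phantoms

The generator produces what the downstream stages need and nothing more:
four disjoint tissue structures (axis-aligned ellipses, one annulus) with
jittered centers confined to image quadrants, on a constant background
(air, -1000 HU, for CT).  Class intensities are piecewise constant plus
additive Gaussian noise (`noise_sigma`, default 5 intensity units / 10 HU),
so noiseless class means equal the intensity table exactly and mean-T2 /
mean-HU recovery is analytically checkable.  MRI phantoms carry a
piecewise-constant T2 map (defaults 35/40/45/20 ms, optional jitter).
Pixel spacing defaults to 0.5 mm isotropic with 2 mm slice thickness.
Default noise values were chosen once as plausible contrast-to-noise for
soft-tissue imaging.

What the phantoms do **not** emulate: anatomy, spatially correlated noise,
intensity inhomogeneity, partial-volume effects, inter-subject variability,
MR physics.  Tests passing on phantoms establish the *mechanics* of the
pipeline (corruption geometry, transfer semantics, metric identities,
optimization behavior), and that SSL pretraining can transfer useful
features in a controlled setting — not clinical performance on real
cohorts.

On-disk format: NIfTI (float32 images and T2 maps, uint8 labels; exact
round trip) or 16-bit PNG with a JSON offset/slope sidecar (round trip
exact to one quantization step), plus a CSV manifest.

## Experiment plans and problem sizes

`ExperimentPlan` defaults define the phantom-scale study: 96x96 images, a
depth-3 U-Net with 8 base filters, 16 unlabeled / 10 labeled / 4 validation
/ 4 test phantoms, batch size 4, learning rate 1e-2 for *both* arms (the
higher end of the learning-rate grid converges best at this model scale;
using the same rate keeps the SSL-vs-supervised comparison fair), up to 15
pretraining and 40 fine-tuning epochs with early stopping.  These sizes
were chosen so the full default plan runs in minutes on one CPU with the
numpy backend; they are not the sizes one would use for real cohorts, where
512x512 images, deeper/wider U-Nets (e.g. depth 5, 32 base filters — both
configurable) and GPU training are appropriate.  96x96 is the smallest size
at which the default strategy's 32x32 Poisson-disc masks are feasible
(`K <= min(H,W)/3`).

The scaling sweep runs the pretraining-data levels {0, 25, 50, 100}% so the
3-parameter power law has 4 distinct x values; its acceptance-script
variant fine-tunes on a half-sized labeled subset because the scaling
benefit is a label-limited phenomenon.  At phantom scale the four sweep
points come from single training runs and are correspondingly noisy; the
fitted exponent can land on its bound and should be read as a demonstration
of the fitting machinery, not as a measured scaling law.

In `run_design_grid`, every strategy is pretrained once, then fine-tuned
identically (same protocol, same seed) across label fractions, with a
supervised baseline per fraction; failing cells are recorded and the run
continues.  All result rows carry the seed and a config hash.

## Repository shape

The fit/transform-shaped pieces are scikit-learn estimators
(`Standardizer`, `PowerLawRegressor`, and the `UNetInpainter` /
`UNetSegmenter` wrappers with `fit`/`predict`/`get_params`); the staged
pretrain → transfer → fine-tune pipeline itself is exposed as plain
functions, which is the natural surface for a multi-stage training
procedure with weight-bundle plumbing.  The CLI is a thin layer over the
library.

## Known limitations

- The numpy backend is single-device and unbatched across processes;
  training at clinical resolution is out of its intended range.
- 3D convolutions, other backbone families, other optimizers and
  contrastive pretext tasks are out of scope.
- `per_volume` normalization treats each 2D image as its own unit in slice
  datasets; true multi-slice volumes are normalized jointly only when
  passed as a single array.
- The Wilcoxon normal approximation is used above n = 12 regardless of tie
  structure; heavy ties at moderate n are better served by lowering
  `exact_max_n` usage thresholds externally if needed.
- Percent errors are reported as magnitudes; signed errors are available in
  the long-format error tables for diagnostics.
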