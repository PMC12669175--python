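# Methods

This note records the modelling and numerical choices behind the package,
what the synthetic phantoms do and do not emulate, and the known limits of
what the test suite demonstrates.

## Conventions

Arrays are indexed `(x, y, z)` (feature grids `(channels, x, y, z)`),
0-based, shapes written `(nx, ny, nz)`; spacing is mm per voxel along
`(x, y, z)`. Sequences formed from grids visit x fastest, then y, then z.

## Preprocessing and harmonization

Resampling uses SimpleITK — trilinear for intensities, nearest-neighbor
for label volumes — to a uniform target spacing (clinical default
0.47 × 0.47 × 6.5 mm); output extent is `round(extent·spacing/target)`,
floored at 1. Cropping reduces only the in-plane axes to the tight
bounding box of nonzero intensity; volumes are then zero-padded
symmetrically to a fixed frame, with the odd voxel on the high-index side
(a fixed, documented convention). An all-zero volume is left uncropped —
total data loss would be worse than a no-op.

Harmonization smooths the image with Gaussian kernels of σ = 0, 2, 4, 6
voxels (σ is interpreted on the already-resampled grid, since
harmonization runs after geometric standardization), z-scores each
smoothed version, rescales it to the matching moments of the smoothed
reference scan, and sums the scales. Moments are computed over the whole
grid (brain-mask-restricted statistics would need a mask that
preprocessing does not produce; the choice is recorded here and is easy to
revisit). Smoothing uses reflect boundaries so intensities near the brain
edge are not pulled toward zero. A constant image raises a
degenerate-input error instead of propagating NaNs: a clinical scan with
zero variance is a data-quality failure. The reference scan is a user
choice, not automated.

## State-space core

The continuous system (A, B, C, Δ) is discretized with the bilinear
transform exactly as written above — not with the zero-order hold that
many implementations substitute — and the fixed-matrix path is available
both as the stepwise recurrence and as the causal convolution with kernel
K̄[j] = C Āʲ B̄; the two are interchangeable to float precision and the
suite checks this on randomized stable systems.

The selective scan stores A as a per-channel negative real diagonal
(initialized to −1…−N per channel, the standard diagonal-SSM recipe),
which makes the bilinear inverse elementwise. Per token, B and C are
linear projections of the token into the state dimension, and Δ is a
per-channel softplus-activated projection (softplus keeps every step size
strictly positive, so the discretization stays well-posed); initial Δ is
log-uniform in [10⁻³, 10⁻¹]. The hidden state starts at zero. The
recurrence is evaluated by a chunked two-pass linear scan (vectorized
inside chunks of ~√L, sequential across chunk summaries) that is
algebraically identical to the naive token loop; correctness is defined by
the naive loop and asserted against it. The projection activations and the
initialization are package choices — the published configuration fixes
only the state dimension (16), a conv width (4) and the expansion ratio
(2).

## MSMS serialization

`build_scan_plan(N, shape)` partitions each axis into N segments (N even;
above 2, a multiple of 4 so the octant traversal below is defined).
Sub-volume s takes one parity class of segment indices per axis; the 8
parity combinations partition the N³ elements. Each sub-volume's 8
element octants are visited in its published traversal order; the orders
pair into four ascending walks of different axis priority (x-, y-,
z-first, and a boustrophedon variant) and their four reversals. Within an
element, voxels are visited in an x-fastest raster whose sense follows the
sub-volume's direction. Element numbering is x-fastest, 1-based. The
traversal order is defined at element granularity — sequences concatenate
whole elements — which is the implemented reading of the published order
tables.

The reversed sub-volumes are exactly the reversed sequences of their
mirrored ascending counterparts, and the 8 sequences start in 8 distinct
parity octants, so the bundle covers the volume from complementary
directions. `multi_merge` inverts `multi_scan` bit-exactly; this is
property-tested and is also what makes the module usable inside a network
(no resampling loss).

The MSMS module is dual-branch: the upper branch scans the 8 sub-volume
sequences (coarse scale, long range), the lower branch scans the single
full-resolution raster. Both branches share one token convention: the
channel axis is the token dimension. Branch outputs are summed —
parameter-free and shape-safe; the fusion operator is otherwise
unconstrained. Grids whose extents are not multiples of N are right-padded
with zeros for the upper branch and cropped after merging (deep layers
have small extents). Whether the lower branch is an SSM or a convolution
is not fixed by the published description; a full-resolution selective
scan is implemented. The published conv width `d_conv` is carried in the
layer configuration but not wired to an operation: the internal wiring it
would parameterize is not specified, and the module implements exactly
scan → SSM → merge plus the dual branch.

The block is LayerNorm → module → residual → LayerNorm → convolutional
feed-forward (two pointwise convs, expansion ratio 2, GELU) → residual.
The SSM output projection and the second feed-forward projection are
zero-initialized, so a fresh block is the identity and residual signal
flows undisturbed at the start of training.

## Network

Six encoder layers (channels 2→32→64→128→256→320→320, state dimension 16)
with kernels (3,3,1) and in-plane-only strides in the first three layers —
the thick-slice geometry is never down-sampled in z early. Each layer is
conv block (stride 1) → MSMS block → strided conv block. Conv blocks are
depthwise + pointwise convolution, instance norm (ε = 10⁻⁵), LeakyReLU
(slope 0.01). The decoder mirrors the encoder: transposed convolution with
kernel equal to the up-sampling factor (taken from the matching encoder
stride — the published decoder stride entries of (1,1,1) for the shallow
layers conflict with resolution restoration and are treated as a
misprint), channel-concatenated skip, conv block. The segmentation head is
a 1×1×1 convolution (the published "1 7 1" is read as a typographical
artifact: pixel-wise classification requires a pointwise head); auxiliary
heads sit at every intermediate decoder resolution.

Input extents must be divisible by the product of the encoder strides;
`predict` z-scores per channel and arg-maxes the logits. The head's
last-class bias can be initialized to the log-odds of the expected
foreground prior (the reduced variant uses −4.6 ≈ 1% prior): with rare
foreground this puts the initial cross-entropy near its optimum, so early
gradients act on the lesions instead of on the background rate — a
standard rare-foreground initialization.

## Objective and training

Per level, loss = ½ CE + ½ Dice. Probabilities come from a 2-class
softmax; CE clamps probabilities to [10⁻⁷, 1−10⁻⁷] (the loss is unbounded
at the endpoints); Dice (ε = 10⁻⁶) is computed on the foreground class
only — under extreme imbalance a background-inclusive Dice is saturated
and uninformative. Deep-supervision weights 1/2ⁱ are normalized to sum to
one so loss magnitudes stay comparable across depths; auxiliary targets
are nearest-neighbor down-sampled (preserves binary labels).

AdamW uses weight decay 0.05 on matrix/kernel weights only — biases,
normalization affines and the state-matrix logs are exempt, the usual
convention — plus global gradient-norm clipping at 1.0. The learning rate
follows cosine decay from 10⁻³ at epoch 0 to 0 at the final epoch.
Training steps are per-volume (z-scored once up front), with optional
in-plane flip augmentation (off by default); k-fold splitting is seeded
and disjoint; fine-tuning loads a checkpoint and restarts the schedule.
Non-finite losses abort with the epoch/volume in the message.

## Evaluation metrics

All ratio metrics derive from voxel confusion counts. Degenerate
denominators follow fixed conventions (Dice/Jaccard 1 when both masks are
empty, 0 when exactly one is; kappa/MCC 0 at degenerate marginals) so
batch averages are always defined. HD95 takes boundary voxels as
foreground voxels with a face-adjacent background neighbor (the volume
border counts as background), measures all nearest-neighbor distances in
physical mm, takes the 95th percentile per direction (linear
interpolation) and the maximum over the two directions; both masks empty
gives 0, exactly one empty gives NaN. Per-subject reports are meant to be
averaged as mean ± sd across subjects.

## Synthetic phantoms

A phantom is an ellipsoidal "brain" support with a smooth random-field
texture (base intensity 100, ±12%), 2 bright ellipsoidal lesions
(multiplicative contrast 1.8, physical radii 2–5 mm) placed at 60–85% of
the support radius — the near-boundary location characteristic of
leptomeningeal lesions — additive Gaussian noise, and a per-scanner affine
gain/offset applied last. Default geometry is 64 × 64 × 12 voxels at
0.47 × 0.47 × 6.5 mm; lesion centers are snapped to slice centers in z so
a 2–5 mm lesion is guaranteed voxel support in 6.5 mm slices. Foreground
stays well under 5% of voxels. The four default scanner profiles differ in
gain (0.72–1.35), offset (−12 to +30) and noise; an optional bright
boundary stripe reproduces the classic false-positive distractor (bright
non-lesion tissue interfaces). All randomness flows through one seeded
generator per phantom.

What the phantoms do **not** emulate: MRI physics (bias fields, k-space
artifacts, partial-volume blur), skulls, anatomical texture, or lesions
with irregular shape. Scanner variation is purely affine, which per-volume
z-scoring alone can remove — so a network passing the smoke test shows the
pipeline is functional and the architecture trainable, not that it matches
clinical performance; and the harmonization test shows moment matching
removes the injected scanner signature, not that it would fully harmonize
real scanners.

## Desk-scale problem sizes

The repository's experiments run on one CPU core, so the standard
configuration is exercised at reduced size: forward-pass contracts use the
full six-layer network on 32 × 32 × 8 inputs, while training experiments
use a two-layer variant (channels 8→16, state dimension 4, head bias
−4.6) on cohorts of 8 phantoms resampled in-plane by 2× to
0.94 × 0.94 × 6.5 mm, 25 epochs, first fold of a 4-fold split (6 train / 2
validation). These sizes are the package's desk-scale defaults in
`msms_seg.experiments`.

## Known limitations

* The network trains volumes one at a time (no batching) on the numpy
  autodiff engine; it is CPU-bound and not intended for full-resolution
  clinical training.
* Only binary (2-class) objectives are implemented; multi-class heads
  construct but the combined loss rejects them.
* `n_segments` other than 2 and 4 requires N/2 even (octant traversal);
  arbitrary even N is not supported.
* Skull stripping, bias-field correction and registration are out of
  scope; inputs are assumed skull-free.
* Complex-valued state spaces are not implemented (real diagonal only).
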