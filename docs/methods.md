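# Methods

## Problem and model family

The package targets automatic delineation of the gallbladder on axial
abdominal CT slices — a small, low-contrast organ that occupies roughly half a
percent of the pixels, so the segmentation problem is dominated by extreme
class imbalance and by look-alike neighboring structures.

Four fully convolutional encoder–decoder architectures are provided:

* **U-Net (baseline).** Five encoder stages, each two same-padded biased 3x3
  convolutions with ReLU; 2x2 max-pooling between stages; decoder stages of
  2x2/stride-2 biased transposed convolutions, skip concatenation and two 3x3
  convolutions; a final 1x1 convolution with sigmoid. No normalization layers.
  With one input channel and channel widths 16/32/64/128/256 this
  configuration has exactly 1,940,817 parameters, which is what pins it: the
  stage structure is the unique "textbook" variant consistent with that count.
* **SEU-Net.** The baseline with a channel squeeze-and-excitation (cSE) block
  after each encoder stage: global average pooling, a bottleneck pair of fully
  connected layers (C -> C/r -> C, reduction r), sigmoid gates multiplying the
  channels.
* **MCA block.** Two composable halves. *Multi-scale feature extraction*:
  three parallel convolutions with kernels 3/5/7 (alternative 5/7/9), each
  emitting the stage's full channel count with ReLU, concatenated and fused
  back by a 1x1 convolution. *Multi-scale channel attention*: the fused map is
  average-pooled (window = stride) at factors 2 and 4; global average pooling
  of the fused map and of both pooled maps yields three per-channel
  descriptors, which are combined and passed through the cSE excitation to
  produce the gates. Each half can be ablated independently; with both off the
  block degenerates to the plain two-convolution stage, giving the
  baseline/extraction-only/attention-only/full ablation grid from
  configuration alone.
* **MCAU-Net.** The baseline with its first 1–3 encoder stages (shallowest
  first) replaced by MCA blocks, and a decoder whose two 3x3 convolutions each
  carry batch normalization, with a 1x1-projection residual shortcut added to
  the second convolution's output before the stage ReLU. Batch-norm running
  statistics are the model's only non-trainable parameters.

### Design choices where the wiring was genuinely open

* **Stage placement of MCA blocks.** Shallowest-first (stage 1 for one block,
  stages 1–2 for two, 1–3 for three): large kernels are most informative where
  spatial detail still exists, and parameter growth stays modest because the
  shallow stages are narrow. Placement is configurable.
* **Descriptor combination.** Element-wise mean of the three scale
  descriptors by default (dimension-preserving and scale-symmetric); sum and
  concat (with a widened excitation input) are selectable. Note an algebraic
  fact: global average pooling commutes with non-overlapping average pooling
  on evenly divisible maps, so the three descriptors are numerically equal and
  mean-combination coincides with a single global pool; the multi-scale
  pathway is retained for fidelity to the block's published structure and
  because the concat variant genuinely widens the excitation.
* **Attention source.** Gates are computed from the fused (Part A) output,
  not the block input.
* **Attention reduction** r = 4. The shallow stages have 16/32/64 channels
  (8 at smoke scale), so the more common r = 16 would collapse the bottleneck
  to one unit.
* **Branch width.** Each multi-scale branch emits the full stage channel
  count before concatenation (rather than a third each).
* **Decoder shortcut.** A 1x1 convolution projects the concatenated skip
  tensor to the stage width and is added before the final ReLU.

## NumPy network engine

The layer stack (`mcaunet.nn`) is a compact reverse-mode automatic
differentiation engine written on NumPy: same-padded stride-1 convolution via
im2col matrix multiplication (input gradients as correlation with the flipped
kernel), 2x2/stride-2 transposed convolution via tensordot, max/average/global
pooling, batch normalization with running statistics (momentum 0.9 — faster
adaptation than the common 0.99, appropriate for runs of a few hundred
steps), dense layers, ReLU/sigmoid, channel gating, and Adam. Every operation
is verified against central finite differences in float64 (`tests/test_nn.py`),
and an end-to-end gradient check runs through the full MCAU-Net graph.
Training uses float32. Weight initialization is He-normal with a seeded
generator, so runs are bit-reproducible given a config seed.

The loss nodes compute the soft Dice loss per image and average over the
batch (preserving each sample's imbalance semantics rather than pooling
pixels across the batch), with smoothing constant eps = 1e-6 default, and
mean binary cross-entropy with probability clamping at 1e-7.

## Preprocessing

`to_hounsfield` applies the scanner's affine rescale; `apply_window` clips to
[level − width/2, level + width/2] and maps linearly to [0, 1]
(monotone in HU); `equalize_adaptive` is CLAHE via scikit-image with the tile
grid translated to a kernel size, returning (near-)constant inputs unchanged;
`normalize01` is min–max rescale with the constant-grid-to-zeros policy so
padding-only slices cannot abort a batch. Defaults — window level 60 HU,
width 400 HU (abdominal soft tissue), CLAHE clip limit 0.01 with 8x8 tiles —
are package choices, configurable throughout; PNG inputs assume identity
rescale, DICOM reads the rescale tags, NIfTI values arrive already scaled.

## Data handling

**Splitting** is by patient, not by slice: slices of one patient are
near-duplicates, and slice-level splitting would leak anatomy across
partitions. Patient counts per partition follow largest-remainder rounding of
the 0.54/0.06/0.40 fractions (ties broken train > val > test); patients are
sorted before the seeded shuffle, so the split is invariant to sample order.

**Augmentation** applies one affine transform — rotation ±15°, shift ±10% of
the side, shear ±10°, zoom ±10%, all uniform draws — identically to image
(bilinear) and mask (nearest neighbor), fills out-of-bounds with zero and
re-binarizes the mask at 0.5. Pre-expansion (`expand_training_set`) retains
originals and appends seeded augmented copies; on-the-fly use is possible by
calling `augment_pair` inside a loader.

## Synthetic phantom generator

The generator emulates the statistics that make gallbladder segmentation
hard, not CT physics. Each phantom (fully determined by `(seed, index)`)
contains:

* a dark abdominal background (0.35 ± smooth noise) holding one large bright
  ellipse ("liver", level 0.65) with smooth internal texture;
* the target: one filled ellipse of random eccentricity (axis ratio
  0.45–0.95) and orientation inside the liver, hypodense by `contrast`
  (default 0.25 — roughly a windowed-and-CLAHE-boosted bile/liver gap), with
  its drawn area jittered ±15% around `fg_fraction_target` x image area so
  the mean fraction over many phantoms concentrates on the target (default
  0.0055, the published imbalance statistic);
* `n_background_structures` distractor ellipses (default 3), the first at
  half the target's contrast — a deliberate look-alike — the rest clearly
  darker or brighter;
* additive Gaussian noise (sd 0.03, ~10 HU on a 400 HU window) and clipping
  to [0, 1].

What passing tests on phantoms do **not** show: real CT texture, partial
volume effects, anatomical variability between patients, multiple organs of
similar intensity in contact with the target, or scanner differences.
Phantom results validate the pipeline's mechanics (losses, gradients,
metrics, schedules, model wiring) and relative model behavior, not clinical
accuracy.

## Metrics

Seven per-case metrics on masks binarized at 0.5 (configurable): DSC, JSC,
PPV, SE, Hausdorff distance, RVD, VOE. HD is the plain symmetric Hausdorff
distance between foreground point sets, Euclidean, in pixel units (a
95th-percentile variant is selectable); RVD is reported as an absolute value
(signed selectable); VOE = 1 − JSC by construction. Degenerate cases: an
empty prediction against non-empty truth scores zeros with RVD = VOE = 1 and
HD equal to the image diagonal; empty-truth cases are excluded from
aggregation and counted, keeping cohort statistics defined without hiding
failures. Aggregation reports mean, sample sd (n−1; a single case reports
sd = 0 with a flag), median, linearly interpolated quartiles, and 1.5-IQR
whiskers clipped to observed data. Metrics are computed per 2D slice.

## Training harness

Adam (default moments), continuous exponential learning-rate decay
`lr0 * rate**(step/steps)` (no staircase), per-epoch validation DSC at
threshold 0.5, checkpoint selection by best validation DSC, divergence abort
on non-finite loss. The shipped full-scale reference presets are batch 4, 80 epochs,
with per-model rates (U-Net 3e-6 constant — its empty decay entries are read
as "no decay"; SEU-Net 6e-5/1200/0.96; MCAU-Net variants 4e-4 or
5e-4/800/0.96).

**Desk-scale sizes.** The smoke configuration trains base-8-channel models on
64x64 phantoms (200 train / 40 validation, 10 epochs); the packaged benchmark
(`run_phantom_benchmark`) uses 120/24/40 phantoms, 6 epochs, and 3 replicate
seeds for the U-Net vs MCAU-Net-2 comparison. Both models share the
5e-4/800/0.96 schedule at this scale: the published per-model rates were
tuned for 80-epoch full-resolution runs, and U-Net's 3e-6 would leave it
essentially untrained in a few hundred steps, making any comparison vacuous.
These sizes are the package's chosen desk-scale study conditions; full-scale
clinical results are out of reach without the (private) clinical data, and the
benchmark therefore checks a directional property (MCAU-Net-2 not worse than
U-Net beyond a small margin) rather than published metric values.

## Known limitations

* The engine is CPU-only and single-threaded NumPy; it is meant for
  desk-scale experiments, not full-resolution clinical training.
* Phantoms carry a single foreground structure; multi-organ contact and
  empty-gallbladder slices occur only as degenerate-policy tests.
* Exact parameter counts are pinned only for the baseline U-Net; the SEU-Net
  and MCAU-Net counts depend on unstated architecture details and are checked
  as ordering constraints.
* HD is in pixel units; converting to millimetres requires slice spacing the
  package does not model.
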