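# Methods

## Problem and model

Pulmonary nodules — lung lesions of 3 mm to 3 cm — occupy well under 1% of
the voxels of a thoracic CT patch, are frequently small (most are ≤ 10 mm),
and sit among vessels and airway walls of similar intensity. `nodseg`
implements a three-level encoder–decoder segmentation network (a 3D U-Net
with residual double-convolution blocks) whose stages are augmented with
four complementary attention mechanisms, plus the loss, tuning and data
machinery needed to train and evaluate it end to end.

The stage plan for a 1×16×96×96 input patch at full width
(`base_channels=64`):

| stage | output shape | attention |
|---|---|---|
| stem (DoubleConv) | 64×16×96×96 | — |
| down 1 | 128×8×48×48 | spatial attention (SA) |
| down 2 | 256×4×24×24 | spatial attention (SA) |
| down 3 | 512×2×12×12 | dilated efficient channel attention |
| up 1 | 256×4×24×24 | CBAM |
| up 2 | 128×8×48×48 | — |
| up 3 | 64×16×96×96 | CBAM |
| output conv | 1×16×96×96 | — |

Squeeze-and-excitation (SE) gates sit on two connections: the 128-channel
encoder skip consumed by up-stage 2, and the 512-channel bottleneck feature
entering up-stage 1. The design intent of "first and last skip connections"
is ambiguous here because the second SE shape (512×2×12×12) matches the
bottleneck output, not a conventional skip; the wiring above is the only one
consistent with all the stage shapes and is isolated in
`AttentionUNet3d.__init__` should a user prefer another.

Each `DoubleConv3d` is conv(3³)–BN–ReLU twice plus a residual connection
(1×1×1 projection, without normalization, when channel counts differ).
Down-stages start with 2×2×2 max pooling; up-stages with trilinear 2×
upsampling (corner-agnostic) followed by skip concatenation. Dropout is
channel-wise at rate 0.1 by default (configurable).

## Attention blocks

* **Spatial attention (SA)** — per-voxel channel mean and max are
  concatenated (2×D×H×W), convolved with a learned 7³ kernel and squashed
  by a sigmoid into a gate in (0, 1) that multiplies the input. Used in the
  two shallow encoder stages where small-nodule spatial detail lives.
* **Dilated ECA** — the C channels are split into four groups, each
  filtered by a depthwise-separable convolution (depthwise dilated k³, then
  pointwise 1×1×1) at dilation rates 1, 2, 5, 7; the concatenated result is
  globally average-pooled to a length-C descriptor, convolved with a 1D
  kernel of channel-adaptive size k = |log₂(C)/γ + b/γ|_odd (γ=2, b=1),
  then passed through ReLU **then** sigmoid. The ReLU floors the gate at
  0.5: the block can only preserve or mildly attenuate a channel, never
  silence it. This rectified-then-squashed form is deliberate, and the
  [0.5, 1) gate range is asserted exactly in tests. Both the
  depthwise kernel size and the 1D kernel use ψ(C) of the full pre-split
  channel count. The nearest-odd rounding breaks ties upward so the kernel
  grows with C (e.g. C=128, t=4 → k=5).
* **CBAM** — channel gate from spatially pooled avg/max descriptors through
  a shared two-layer MLP (hidden C/r, ReLU), then a spatial gate identical
  in form to SA. The default aggregates the two MLP outputs **before** a
  single sigmoid, keeping the gate in (0, 1); the alternative of applying
  a sigmoid to each branch before adding yields a gate in (0, 2) and is
  available as `cbam_gate_mode="per_branch_sigmoid"`.
* **SE** — global average pool → FC(C→C/r) → ReLU → FC(C/r→C) → sigmoid →
  per-channel recalibration. Reduction r defaults to 16 (hidden width is
  floored at 1 when C < r).

All blocks preserve the input shape exactly and are verified against naive
nested-loop float64 reference implementations to 1e-5 on random inputs.

## Loss

Training minimizes

    L = w1·L_BCE(α) + w2·L_Dice + w3·L_IoU,  w1+w2+w3 = 1,

on sigmoid probabilities: a voxel-weighted binary cross-entropy with
positive-class weight α (probabilities clamped to [1e-7, 1−1e-7]), the soft
Dice complement 1 − (2Σpy+ϵ)/(Σp+Σy+ϵ), and the soft IoU complement with
union Σp+Σy−Σpy. Defaults are the swarm-optimized mixture w = (0.2093,
0.4702, 0.3205) with α = 1.56; the smoothing ϵ defaults to 1e-5
(configurable). Losses consume soft probabilities;
evaluation metrics (DSC, sensitivity, precision) consume hard masks at
threshold 0.5, computed per volume and macro-averaged. Degenerate volumes
follow the conventions: DSC = 1 when both masks are empty, SEN = 1 when
there is nothing to find and nothing was predicted (0 if false positives
exist), symmetrically for PPV — necessary for nodule-free patches.

The training loop uses an algebraically identical fused logits-to-loss
operation with a closed-form gradient; equality with the composed
definition is asserted in tests.

## Hyperparameter search

`pso_tuner` is a canonical particle swarm over (weight_decay, w_bce,
w_dice) minimizing a fitness callback (negative validation Dice in the
tuning application): v ← wv + c₁r₁(p_best−x) + c₂r₂(g_best−x), positions
clipped to the box each step. The IoU weight is derived as
w_iou = max(0, 1 − w_bce − w_dice), which keeps the mixture on the unit
simplex — consistent with the default optimized triple, whose three weights
sum to 1. An alternative coupling that derives the IoU weight from the BCE
weight alone, `iou_weight = max(0, 1 − bce_weight)`, is available as
`simplex_mode="literal"`; it cannot produce a triple summing to 1 when the
Dice weight is positive, which is why it is not the default.
Swarm hyperparameters default to standard
practice (n_pop=10, max_iter=20, w=0.7, c₁=c₂=1.5) with bounds
weight_decay ∈ [1e-5, 1e-2] (sampled log-uniformly), w_bce ∈ [0.1, 0.6],
w_dice ∈ [0.2, 0.7]. Fitness values are cached by position rounded to six
decimals so a re-visited candidate is not re-trained.

## Training configuration

The full-scale recipe (`configs/luna16_full.yaml`) is 200 epochs, batch 4,
AdamW with weight decay 5.17e-4, initial learning rate 1e-3 decayed
linearly (lr(t) = lr0·(1 − t/epochs)), the loss defaults above, and
augmentation by random axis flips, in-plane 90° rotations and Gaussian
intensity noise (σ = 0.01) on the image only. Rotations are restricted to
90° multiples in the axial plane because the patches are ~3× anisotropic
along z, so arbitrary-angle 3D rotation is not label-preserving on this
grid. The checkpoint with the highest validation Dice is kept. Adam and
RAdam are implemented alongside AdamW for the optimizer-comparison harness,
which also reports pooled voxel-level F1 (micro) next to the macro Dice —
the two coincide in form but differ in aggregation — and mean epoch time,
which is hardware-dependent and never asserted.

## Preprocessing

CT volumes (MetaImage, HU) are multiplied by their binary lung masks,
clipped to a Hounsfield window of [−1000, 400] (the standard lung
window), min-max scaled to [0, 1] over in-mask voxels,
demeaned within the mask (so background zeros do not bias the mean), and
resampled to (2.0, 0.7, 0.7) mm (z, y, x) — trilinear for intensities,
nearest-neighbour for masks. At that spacing a 16×96×96 patch spans
32×67×67 mm, enough to contain a 30 mm nodule. Masking + normalization is
idempotent: min-max scaling is invariant to the affine shift the demeaning
applies, and the HU window contains the normalized range, so a second
application is a no-op. Ground-truth masks come from per-slice nodule
contours in LIDC-style XML, filled per slice with inclusive edges, matched
to slices by world z-position (tolerance half a slice), and combined across
reading sessions by a ≥ 50% consensus vote by default — a documented
choice, since no single canonical mask-construction rule exists.

## Synthetic phantoms

The generator emulates the *structure* of preprocessed nodule patches, not
lung anatomy: a smooth parenchyma texture (background level 0.1, texture
σ ≈ 0.05), Poisson-many bright tube segments standing in for vessels
(≈ 3 per patch, radius 0.7–2 mm, intensity +0.5 — deliberately as bright as
or brighter than nodules, the main confuser the attention mechanisms
target), white Gaussian noise, and at most one nodule per patch. Nodules
are ellipsoids whose radius is modulated by a random quadrupole-like
angular harmonic (amplitude 0.2, bounded by tanh) to imitate lobulation,
voxelized by 3³ subvoxel sampling (a voxel is positive at ≥ 50% coverage),
with intensity added as contrast × coverage so edges show partial-volume
softening.

Defaults and their provenance:

* diameter: log-normal, median 6 mm, σ_log 0.45, truncated to [3, 30] mm —
  chosen so ≥ 80% of nodules are ≤ 10 mm, the documented size skew of the
  screening population, while keeping the dataset's positive-voxel fraction
  under 1%;
* contrast 0.6 and noise σ 0.03, in normalized-image units, derived from HU
  arithmetic: on a [−1000, 400] window scaled to [0, 1], parenchyma
  (≈ −850 HU) to solid-tissue nodule (≈ +30 HU) is ≈ 0.63, and 25–40 HU of
  CT noise is ≈ 0.02–0.03;
* 20% of patches contain no nodule.

What passing tests on phantoms do **not** show: performance on real CT.
Phantoms have no pleural or juxta-vascular attachment, no ground-glass
texture, no scanner-specific noise correlation, and a single nodule per
patch; results on them demonstrate that the pipeline is wired correctly
and that the network can learn the intended discrimination, not that it
reaches any particular clinical accuracy.

A raw-HU mode (`synthetic_thorax`) renders a soft-tissue block with an
air-filled lung ellipsoid and a solid nodule for exercising the
preprocessing pipeline end to end.

## CPU-scale studies

Full-scale training (64 base channels, 888 scans, GPU) is out of reach of a
test suite, so the package defines two reference studies, run by the test
suite and the acceptance script:

* **Learning study** — the enhanced architecture at `base_channels=4`
  (attention reductions 4), 64 training and 16 validation default phantoms
  of the full 16×96×96 geometry, 30 epochs, batch 4, AdamW, the optimized
  loss mixture. Width is the only architectural change from the full-scale
  model. On one CPU core this sits around a quarter hour; the best
  validation Dice lands well above 0.8.
* **Directional ablation** — baseline vs enhanced at reduced size
  (16×48×48 phantoms, contrast 0.45, 24/12 patches, 15 epochs, 3 seeds).
  The conditions were chosen so that no variant floors or saturates —
  at default contrast every variant nails the task and the comparison is
  uninformative; at very low contrast and very short schedules nothing
  learns and the comparison is noise. The claim checked is directional
  only: mean best validation Dice of the enhanced variant ≥ baseline.

## Numerical choices

The compute core is a small reverse-mode autodiff tape over NumPy arrays
(float32 throughout) with numba-compiled direct convolution kernels;
unit-dilation convolutions of width 3 and 7 use tap-fused specializations,
and an im2col + GEMM fallback covers environments without numba. Batch
normalization in training mode is a single fused taped operation with the
standard closed-form backward. Convolution adjoints are verified by
dot-product (transpose) identities and against loop references; attention
blocks and the full network are verified against float64 loop oracles.
Gradient determinism: identical seeds reproduce identical weights
bit-for-bit; all randomness flows from explicit `numpy.random.Generator`
objects.

Degenerate inputs: even kernels, channel counts not divisible by the four
dilation groups, odd spatial dimensions entering a pooling stage, input
dimensions not divisible by 8, mismatched skip shapes, annotations outside
the volume, truncated MetaImage payloads, and simplex-violating loss
weights all raise immediately with messages naming the violated constraint.

## Known limitations

* No 2D variants, deep supervision, multi-class output, mixed precision,
  test-time augmentation or ensembling.
* Full-scale accuracy on the real screening dataset is not reproducible
  here (GPU-scale training on an external download) and is not asserted
  anywhere; the package ships the recipe, not a headline number.
* DICOM ingestion and automatic lung-mask computation are out of scope
  (masks are consumed as provided).
* The CPU autodiff core favours clarity and exactness over throughput;
  batch sizes beyond ~8 at full width are impractical on one core.
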