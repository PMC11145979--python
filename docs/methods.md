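# Methods

## Model family and assumptions

The family is a sequence of VGG11 variants for K-class image classification
at 224×224 RGB input (any multiple of 32 is accepted; the five 2×2 max pools
divide the side by 32, so 224 → 7×7 before the head). All variants share the
eight-stage convolutional trunk with pools after stages 1, 2, 4, 6 and 8.

* `vgg11`: channel plan 64,128,256,256,512,512,512,512, 3×3 convolutions
  with bias, no normalisation, three fully connected layers
  (25088→4096→4096→K) with ReLU and dropout 0.5.
* `re_vgg11`: channel plan reduced to 32,64,64,64,128,128,256,256, batch
  normalisation after every convolution, FC widths 1024. Convolutions keep
  their bias terms (so the budget of this baseline counts conv biases and
  BN affine pairs).
* `scheme1..3`, `g_ppw_vgg11`: the nested option grid described in the
  README. Stage 1 always stays a dense convolution: with 3 input channels a
  partial split is meaningless.

ReLU is the activation throughout. Dropout appears only in the FC heads.

## Operator conventions

**PConv block** = partial k×k convolution over the first `cp = ⌊r·C_in⌋`
channels (bias-free) → concatenation with the untouched channels → 1×1
pointwise mix `C_in→C_out` → optional BN → ReLU. The convolved subset is the
*first* `cp` channels, a fixed deterministic choice; r defaults to 1/4.

**PMConv block** = the same with the `cp` subset partitioned into
`len(kernel_set)` contiguous groups of near-equal size (remainder assigned
to the trailing groups, e.g. 64 → 21/21/22) and kernels assigned in
ascending order (3, 5, 7 by default). Groups are dense within-group
convolutions (`cp_i → cp_i`), not depthwise.

**ECA** computes per-channel means, convolves the length-C mean vector with
a single k-tap kernel and gates each channel by the sigmoid of the result.
k follows the adaptive odd rule `⌊|log2 C + b|/γ⌋`, bumped to odd, clamped
at ≥ 3 (γ=2, b=1; the raw rule gives a degenerate k=1 for C ≤ 8). The 1-D
convolution uses *edge* (replicate) padding rather than zero padding: with
zero padding the two border channels of a perfectly uniform input would
receive different gates than interior channels, breaking the natural
symmetry of the gate under channel permutation of an equal-mean input. The
choice costs nothing (the kernel is the only parameter, k values) and makes
that symmetry exact.

**Bias / normalisation bookkeeping.** The lightweight presets
(`scheme1..g_ppw_vgg11`) run their convolutions bias-free wherever BN
follows (the BN shift absorbs a bias), and the pointwise head is fully
affine-free (no BN, no biases): `PW(256→1024, no bias) → ReLU →
PW(1024→K, no bias) → GAP`. These conventions are part of the preset
definitions because they are what reproduces the published two-decimal
parameter-memory grid (1.78 MiB for the PConv+head scheme, +0.01 MiB for
PMConv, 1.79 MiB for the final model) — with affine pairs and biases
everywhere the grid lands on 1.80/1.81 instead. The dense baselines keep
their published conventions (conv biases; BN affine pairs in the reduced
baseline). The operator classes expose `use_bn`/`pw_bias`/`bias` flags, so
either convention can be built explicitly.

The published budget for the PConv-only scheme (`scheme1`) cannot be
reconciled with any bias/BN convention of the stated architecture (its FC
head alone exceeds the printed figure); the preset is provided, but its
budget is not asserted anywhere.

## Budget accounting

Parameter counts enumerate every learnable tensor; memory is
`count × 4 bytes / 2^20`, reported to two decimals. A ±0.01 discrepancy on
these two-decimal figures is treated as reporting-convention rounding. BN
contributes its 2C affine values; running statistics are not learnable and
are not counted. The head share (`head_fraction`) counts everything after
the last pooling stage; for the reduced baseline this recomputes to 92.04%
against a published 92.02% — within the same reporting noise, as no nearby
convention reproduces the printed value exactly.

MACs are counted per layer at a stated input size: convolution/linear
multiplies, plus (by default) one add per biased output element and one op
per activation element; pooling and BN are excluded by default. All four
terms are independent flags (`MacConvention`), because the tool behind the
published complexity figures is unidentified; under the default convention
the VGG11 total lands within 0.02% of the published 7,618.57 M. The
published complexity column for the lightweight presets is not reproduced
by any flag combination (this package counts a much larger saving from
partial convolution than published) and is therefore not asserted; the
worked reduction examples use the published figures as inputs.

## Dataset protocol

Augmentation order: independent vertical/horizontal flips (p = 0.5 each) →
rotation uniform in [−30°, +30°] with reflect padding, bilinear resampling →
photometric jitter → random 300×400 crop → bilinear resize to 224×224.
Jitter factors are uniform in [0.9, 1.1]: brightness and saturation multiply
the V and S channels (clipped to [0, 1]); the hue factor shifts H by
0.25·(factor − 1) — a bounded rotation of at most ±0.025 hue units, since a
multiplicative hue change has no physical meaning on a circular axis. All
draws flow from a single seed and the pipeline is byte-deterministic. The
per-image augmentation multiplicity is a caller decision, not inferred.

Splits are stratified 60/40 (train/test) or k-fold (default 3) with
shuffling, driven by one seed. Directory datasets follow the
`root/<class>/*.png` layout with lexicographic class ordering.

The mobile-app rule resizes any image whose longer side exceeds 300 px to
300×300 before the final 224×224 resize; smaller images resize directly.

## Synthetic canopy generator

Each class is an oriented sinusoidal stripe texture (orientation θ_c,
frequency f_c cycles/image) rendered in a green hue band centred at h_c,
composited over a brown low-frequency clutter background through a smooth
coverage mask, plus additive Gaussian pixel noise. Defaults give six
classes with orientations 30° apart, frequencies 8–18, hue spacing 0.025
(easy), noise σ = 0.03 and 10% background visibility; `medium`/`hard`
shrink the hue spacing and raise noise and clutter. Signatures must be
pairwise distinct and generation is a pure function of (spec, seed).

The generator emulates the *structure* of the classification problem —
class-conditioned oriented texture and colour statistics over a cluttered
background — not its photometric difficulty: real canopy images vary in
illumination, scale, blur and occlusion in ways this model does not.
Passing the desk-scale pipeline (≥90% held-out accuracy on easy data)
demonstrates that the architectures, optimiser and metrics are wired
correctly and that the training loop can extract a genuine signal; it says
nothing about accuracy on real field data.

## Training

AdamW (β = 0.9/0.999, decoupled weight decay 0.01), cross-entropy loss,
initial learning rate 0.005 halved on a fixed cadence. The published
schedule (`TrainConfig.table4`) uses batch 112 for 120 epochs; the decay
cadence is not published and defaults to every 30 epochs, exposed as
config. The desk profile (`TrainConfig.desk`, and the estimator defaults)
uses 32 px inputs, batch 32, 20 epochs, decay every 8 — sized so a full
synthetic experiment runs in seconds-to-minutes on one CPU core. The
trainability property check runs 200 optimiser steps per preset (60 for the
128 M-parameter baseline) on 64 images at 32 px; the cross-validation and
end-to-end checks use 300 images at 32 px. These sizes are the package's
desk-scale choices, stated here so they can be scaled up deliberately.

## Numerical choices

* All layer arithmetic is float32 by default (float64 available per layer;
  the gradient tests run in float64 against central differences).
* Batch norm uses biased batch variance, ε = 1e-5, momentum 0.1.
* Max-pool ties resolve to the first element of the window; argmax
  prediction ties resolve to the lowest class index.
* F1 is defined as 0 when P + R = 0; precision/recall are 0 when their
  denominators vanish.
* Cross-entropy is computed in float64 with probabilities clipped at 1e-12.
* The softmax-score AUC is macro one-vs-rest and is reported only when all
  head classes appear in the evaluation labels.

## Limitations

* Stride is fixed at 1 with same padding; downsampling is pooling-only (all
  architectures here need nothing else).
* Training on one CPU core is practical at desk scale only; the published
  224 px/120-epoch schedule would take days in this engine.
* The synthetic benchmark upper-bounds nothing about real-field accuracy
  (see above); published real-data accuracies are out of scope.
* Checkpoints store raw arrays (`.npz`) plus the architecture config; no
  cross-framework export.
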