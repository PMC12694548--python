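# Methods

This note documents the models, procedures and design choices behind the
`icsms` package: a lightweight convolutional classifier family for
fine-grained grape-leaf cultivar identification, together with the synthetic
benchmark used to test it.

## The classification problem

Eleven grape cultivars are distinguished from photographs of single leaves
taken in working vineyards: cluttered backgrounds (soil, grass, vine
trunks), variable lighting and pose, and partial occlusion of the leaf by
other vegetation. The discriminative signal is morphological — lobe
structure, margin serration, vein geometry, hue — and much of it is
spatially organized (serration lives on the margin, veins radiate from the
petiole), which motivates attention mechanisms that encode *position* and a
fusion stage that preserves *fine texture*.

## Model family

### Backbone

The backbone is MobileNetV3-Small: a stride-2 stem (16 channels), eleven
inverted-residual bottlenecks ("expand 1x1 → depthwise k×k → attention →
project 1x1", residual when stride 1 and widths match), a 1x1 head
convolution to 576 channels, global average pooling and a 1024-hidden
classifier. The eleven bottleneck rows are stored as data
(`backbone.MOBILENET_V3_SMALL_ROWS`) so variants can rewrite the attention
column wholesale. Hard-swish / hard-sigmoid use the piecewise-linear forms
`x·relu6(x+3)/6` and `relu6(x+3)/6`.

Conventions that affect the parameter budgets: convolutions followed by
batch norm carry no bias; batch-norm affine parameters are trainable and
counted, running statistics are buffers and are not; the classifier keeps
the canonical dropout 0.2 (contributes no parameters). Weight
initialization is Kaiming-uniform for convolutions and N(0, 0.01) for
linear layers, all drawn from a single seeded generator so any variant is
bit-reproducible.

### Attention variants

Four interchangeable gating blocks can sit at the SE position of each
bottleneck, all shape-preserving and all the identity when their gates
saturate at one:

* **SE** — global average pool → bottleneck MLP (squeeze width
  `make_divisible(C/4, 8)`) → hard-sigmoid channel gates.
* **ECA** — a k-tap 1-D convolution over the pooled channel descriptor
  (adaptive odd k from the channel count); only k parameters per block.
* **CBAM** — channel gate from avg- and max-pooled descriptors through a
  shared MLP, then a spatial gate from channel-avg/max maps through a 7×7
  convolution.
* **CA (coordinate attention)** — pooling factorized along H and W; the two
  axis profiles are concatenated, mixed by a shared 1x1 convolution
  (BN + hard-swish), split, and turned into per-axis hard-sigmoid gates
  applied as `x · a_h · a_w`. This is the block the final model uses: it
  keeps channel selectivity while encoding where along each axis the
  informative activations sit.

Two reduction ratios are pinned by the published whole-model budgets rather
than by upstream defaults, because the budgets are the only constraint the
study states: the CA bottleneck ratio is r = 9 (giving the swapped model
1,373,988 parameters, i.e. 1.37 M), and the CBAM variant uses channel
reduction 4 (1,524,413 → 1.52 M), the same reduction family as the SE
blocks it replaces. The CBAM instance inside the fusion stage keeps the
canonical reduction 16, where the 576-channel width makes that the
budget-consistent choice. A true ECA swap yields 1,067,530 parameters
(1.07 M): ECA is three orders of magnitude lighter than the other blocks,
and no genuine ECA definition reaches the 1.52 M sometimes quoted for an
ECA variant of this backbone; the audit therefore reports the computed
value and the target table carries no ECA row.

### ICS-Inception fusion stage

The fusion stage replaces the backbone's final bottleneck stage (the two
576-expansion blocks and the head convolution) and fuses two views:

* three branches on the deep 96-channel 7×7 feature — 1x1 linear
  (conv+BN), 1x1 + ReLU6, and 3×3 stride-1 max-pool followed by a 1x1
  projection (widths 128 / 96 / 64);
* a high-resolution detail branch on the 24-channel 28×28 stage-2 feature —
  1x1 ReLU6 expansion to a 672-channel texture basis, 1x1 linear projection
  to 288 channels, then 4×4 average pooling down to 7×7.

The concatenation is exactly 576 channels, so the classifier head is
unchanged; CBAM (reduction 16) filters the concatenation channel-then-
spatially. The high-resolution tap is what gives the model its
multi-scale character: vein- and serration-scale texture no longer survives
at 7×7, so a purely deep Inception block could not carry it.

Branch widths were solved by a small grid search under three simultaneous
constraints: concat = 576; total trainable parameters of the CE-only
assembly round to 1.12 M; multiply-accumulates at 224×224×3 round to
0.21 G. The shipped solution (1,120,684 parameters; 207.2 M MACs) is
recorded in the audit manifest. A placement note: any block operating only
at 7×7 adds MACs = 49 × (its parameters), so a compute budget of 0.21 G
against a parameter budget of 1.12 M *forces* most fusion arithmetic to run
at a higher resolution — the 28×28 tap is the coarsest placement that
satisfies both numbers at once.

The comparison variant "MS-CA-I" replaces the same stage with a
conventional single-scale Inception block (1x1 / 3×3 / 5×5 / pool branches,
widths 224/96→128/32→96/128; 1,073,572 → 1.07 M).

### Joint supervision

Training minimizes `L = L_CE + λ·L_center`, where `L_CE` is the batch-mean
cross-entropy (natural log) and

    L_center = 1/2 Σ_i ‖f(x_i) − μ_{y_i}‖²

is a batch *sum* (the conventional form for this loss; λ absorbs the scale
difference, and the sweep values {0, 0.01, 0.05, 0.1, 0.2} are used as-is,
default 0.01). The center features f(x) are a learned affine projection of
the pooled 576-d feature to d_c = 85 dimensions; d_c is pinned by the
published parameter increment of the joint-loss model (1.12 → 1.17 M:
projection 576·85+85 plus the 11×85 center matrix = 49,980 ≈ 0.05 M). The
form of the head (affine, no nonlinearity) is a reconstruction forced by
that increment and is flagged as such in the audit manifest.

Centers are not optimized by backprop. They follow the canonical mini-batch
update of discriminative feature learning,

    Δμ_j = Σ_{i: y_i=j} (μ_j − f_i) / (1 + n_j),    μ_j ← μ_j − α·Δμ_j,

applied by plain SGD with α = 0.5, separate from the Adam optimizer
(lr 1e-4) that trains the network weights. The gradient of `L_center` with
respect to f(x_i) is (f(x_i) − μ_{y_i}); centers are constants inside the
loss. With λ = 0 the joint path is bit-identical to CE-only training (the
projection receives no gradient and the logits path is untouched) — this
degeneracy is asserted by a test.

## Budget accounting

`count_parameters` counts trainable scalars (conv/linear weights and
biases, BN affine pairs, the center projection and center matrix on the
joint model). `count_macs` counts one multiply-accumulate per weight
multiply for conv and linear layers at batch 1 — the convention most
lightweight-CNN papers print under the label "FLOPs"; the audit labels its
column the same way. Rounding follows the printed precision: millions to 2
decimals (1 for MobileNetV3-Large), G to 2 decimals.

Headline parameter *reductions* are quoted from the printed-precision
budgets truncated at one decimal — (1.53−1.37)/1.53 → 10.4%,
(1.53−1.17)/1.53 → 23.5% — the convention under which both published
figures are reproduced simultaneously; the audit also reports the
exact-count ratios (10.1% and 23.4%), which differ because rounding to
2 decimals is lossy at this magnitude.

Reference baselines (ResNet-50, MobileNetV2, MobileNetV3-Large,
ShuffleNetV2 x1.0) are the canonical ImageNet architectures with the final
classifier resized to 11 classes; they exist to validate the counters
against well-known budgets (23.53 M / 2.24 M / 4.2 M / 1.26 M).

## Numerical core

The network stack runs on a compact reverse-mode autodiff engine over
float32 numpy arrays (`icsms.nn`): tape-based `Tensor`, fused conv2d
(pointwise fast path via matmul, depthwise via kernel-offset accumulation,
dense via im2col), max pooling (tie gradients routed to every maximal
cell), batch norm (batch statistics in training, running statistics in
eval; running variance uses the unbiased estimator), and a fused
softmax cross-entropy. Every op's backward pass is verified against central
differences in the test suite. Computation is deterministic given the
seeds; there is no multi-threaded nondeterminism beyond BLAS, which is
bitwise stable for fixed shapes here.

## Data pipeline

Images are loaded as float RGB in [0, 1], resized bilinearly to 224×224 and
normalized per channel (mean 0.5, std 0.5 by default; ImageNet statistics
selectable). Training-split augmentation mirrors the field-robustness
recipe: horizontal flip p = 0.5; rotation uniform in [−15°, +15°] with
reflect padding; independent multiplicative brightness and contrast jitter
in [0.9, 1.1] (the "±10%" read multiplicatively); 3×3 Gaussian blur with
p = 0.3, σ ~ U[0.1, 2.0] (only the kernel size is prescribed; the σ range
spans negligible-to-saturating blur at that kernel). Validation and test
images are never augmented.

Splitting is stratified per class: validation and test each receive
`round(0.1·n)` images, training the remainder. On the study's per-class
totals (528, 360, 666, 623, 366, 726, 353, 696, 600, 713, 420; 6051 total)
this reproduces the published 4839/606/606 partition exactly — a
floor-plus-largest-remainder rule does not (it yields 4843 training
images), which is why the nearest-integer rule was adopted. k-fold
assignment is stratified with per-class fold sizes differing by at most
one; every sample sits in exactly one fold.

## Synthetic benchmark

The generator emulates the statistical structure of the field dataset, not
its pixels: eleven classes separable by construction, cluttered multi-
element backgrounds, and a controlled occlusion profile. A leaf is a polar
curve `r(θ) = R(1 − depth·sin²(lobes·θ/2)) + serr_amp·R·sin(serr_freq·θ)`
with a radial vein skeleton and HSV-space coloring; the eleven presets are
pairwise distinct in at least two parameters and unique in the
(lobes, serr_freq) pair. Scenes compose the sprite (random pose, jittered
placement, lighting factor 0.8–1.15) over a canvas tiled from 2–4
value-noise element textures (soil / grass / trunk palettes), then draw
textured capsule occluders until the leaf-mask occlusion fraction falls in
the requested band (<15%, 15–30%, 30–40%; band mix 65/25/10 apportioned by
largest remainder per class). Occlusion is measured on the ground-truth
mask, and the achieved fraction is recorded in the manifest.

What passing tests on this benchmark do and do not show: they demonstrate
that the architecture trains, that the optimization contracts hold, and
that joint supervision compacts the feature space on a learnable task; they
do not certify accuracy on real vineyard photographs, whose texture
statistics, class overlap and annotation noise the generator does not
model. A nearest-centroid classifier on oracle shape descriptors (lobe
count and serration frequency recovered from the silhouette's radial
spectrum) separates the synthetic classes with >95% accuracy, so failure to
learn would indicate a pipeline defect rather than an unlearnable task.

## Desk-scale benchmark conditions

The study-scale experiment (6051 images at 224×224, batch 64, 200 epochs,
~15,000 optimizer steps) is far beyond a single-CPU budget, so the shipped
benchmarks run scaled down, with conditions chosen once and fixed:

* dataset: the tiny preset, 20 images/class (220 images, 80/10/10 split);
* input resolution 96×96 (the architecture is resolution-agnostic above
  ~32 px: global pooling absorbs the spatial size);
* batch 16 — the study batch of 64 would give 3 gradient steps per epoch
  on 176 training images;
* Adam lr 1e-3 rather than the study's 1e-4, compensating a ~70× shorter
  schedule (220 steps in the 20-epoch benchmark);
* augmentation on, except in the 2-class memorization probe (a pure
  capacity/optimizer check, 64×64 inputs, λ = 0, ≤50 epochs).

Under these conditions the 20-epoch benchmark reaches several times the
11-class chance rate, the λ = 0.01 runs show smaller mean intra-class
center-feature distance than matched λ = 0 runs (3-seed average), and the
memorization probe reaches 100% training accuracy.

## Known limitations

* Real-image accuracy (the headline ~96.5% on the 11-cultivar photograph
  dataset) is not reproduced here; it requires the external dataset and
  GPU-scale training. The training CLI supports it unchanged.
* The numpy core is single-threaded-CPU oriented; throughput is adequate
  for the benchmarks and audits, not for 200-epoch 224×224 training.
* The ICS-Inception internals (branch count, widths, the high-resolution
  tap, CBAM placement after concatenation) are a reconstruction pinned by
  the published parameter and compute budgets; other internals matching the
  same budgets exist.
* Occluders are drawn over the leaf only after background composition, so
  occlusion never correlates with pose or lighting as it can in the field.
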