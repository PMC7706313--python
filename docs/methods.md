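# Methods

## The layer-graph engine

`netcore` implements the minimum needed to *interpret* a CNN rather than to
train one at scale: a DAG of typed layers (conv2d, batchnorm, ReLU,
max/average pooling, global average pooling, dense, channel concat,
softmax) whose weights are plain numpy arrays.

Conventions, fixed once to prevent coordinate drift across modules:
channels-last `(N, H, W, C)` float64 arrays, row-major, origin top-left,
spatial sizes reported H×W; pixel values in [0, 1].  Convolution and
pooling support `same`/`valid` padding; `same` pads to ⌈in/stride⌉ with the
asymmetric remainder after the window.  Average pooling excludes padding
from its denominator.  Batchnorm uses moving statistics (inference mode)
everywhere except inside the training loop — visualization is defined on a
fixed trained function.  Batchnorm carries an optional learnable scale;
the InceptionV3-like builder disables it (shift + moving mean + moving
variance, three parameters per channel), which is the convention under
which the architecture's published totals — 21,880,646 parameters for the
full 38-class model and 5,167,878 after truncation at Mixed5 — are
reproduced exactly.  Parameter reports include the moving statistics in
the total while flagging them non-trainable.

### Backward propagation rules

The same reverse-topological sweep serves three unit rules:

* **vanilla** — exact analytic gradients (validated against central finite
  differences at 1e-4 on randomly initialized graphs);
* **guided** — at each ReLU the backward signal is zeroed where the forward
  pre-activation *or* the incoming backward signal is negative; it reduces
  to vanilla when all pre-activations are positive;
* **rescale** — DeepLIFT-style multipliers against a reference forward
  state: at ReLUs the multiplier is Δout/Δin (activation differences
  against the reference), with a gradient fallback when |Δin| < 1e-7; at
  affine layers the exact linear rule applies.  On affine+ReLU graphs the
  input contributions mᵢ·(xᵢ−refᵢ) sum to F(x)−F(ref) to machine
  precision (summation-to-delta).  Max pooling is not elementwise, so the
  rescale sweep routes it by the gradient of the actual input — the usual
  practice — and exact conservation is then only guaranteed on pool-free
  graphs.

Backward targets are composable seeds: a class's pre-softmax logit, a
channel's spatial-mean activation, or an arbitrary weighted sum over a
layer.  Cross-entropy training seeds `(softmax − onehot)/batch` directly at
the logits.

### Architecture builder, truncation, training

`build_inception_v3_like` reproduces the canonical InceptionV3 channel
plan (stem Conv1–Conv5, modules Mixed0–Mixed10, feature depth 2048, Mixed5
depth 768) with a GAP + dense head.  The padding dialect is `all_same` by
default so a 224×224 input reaches Mixed10 at 7×7 (the documented spatial
size at that resolution); a conventional valid-padded stem is available as
`standard_stem`, and the parameter count is identical under both.

`truncate_at` performs layer shaving: the ancestor closure of the cut layer
is kept with its weights, and a fresh GAP + dense + softmax head sized to
the cut layer's channel depth is attached.  Cutting at the last feature
layer is identity surgery (same parameter total).

`train` is Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) on categorical cross-entropy
with batchnorm batch statistics (momentum 0.9) during training, per-epoch
train/validation history, and model selection at the lowest validation
loss.  `TrainConfig` documents the full-scale defaults (lr 0.05, batch
128); the fixture models train with lr 0.01, batch 32, 15 epochs — small
data needs a gentler rate.  Frozen layers skip both weight updates and
moving-statistic updates.

## Synthetic leaf data

`synthgen` emulates the structure of single-leaf disease datasets at desk
scale, not their photorealism: one randomly placed/rotated elliptical leaf
on a uniform background, lesions painted as disks (solid, or ringed with a
dark center and lighter halo) clipped to the leaf, Gaussian pixel noise
(sd 0.02) applied after the binary lesion mask is recorded, everything
clipped to [0, 1].  Default images are 64×64 so the fixture CNN trains in
seconds.  The default task has four classes on a shared background and leaf
color — healthy; large brown solid lesions; ringed lesions with a yellow
halo; small dark dense specks — so lesion appearance is the *only*
class-discriminative feature and attention is expected on lesions.

Splits follow a 6:2:2 ratio per class: ⌊0.6n⌋ train, ⌊0.2n⌋ validation,
remainder test (n=10 gives exactly 6/2/2); sampling is
seed-deterministic via per-(class, index) seed sequences.

What passing tests on this generator do **not** show: robustness to
field imagery (cluttered backgrounds, occlusion, lighting), to lesions
defined by texture rather than color, or to class counts beyond a handful.
The fixture results are scaled-down analogs — they demonstrate that the
implementations behave as the methods claim under controlled conditions,
not that the methods work on any particular real dataset.

## Visualization choices

**Hidden layers.**  Channels are min-max normalized independently (a
constant channel maps to zero) and tiled row-major into a ⌈√c⌉-wide grid
with 1-px separators — per-channel normalization keeps every tile visible.
Shannon entropy converts RGB to grayscale with ITU-R 709 luminance weights
(0.2125, 0.7154, 0.0721), quantizes to 8 bits and sums −p log₂ p (0–8
bits); it matches scikit-image's entropy on quantized input and is
permutation-invariant.

**Feature visualization.**  Images are parameterized as complex half-plane
spectra per color component.  The render path multiplies coefficients by a
1/frequency scale (capped at the image scale, times √(HW)), inverse-FFTs,
mixes colors through a fixed 3×3 decorrelation matrix (the widely used
empirical natural-image RGB factor, normalized by its largest column norm;
a data-estimated Cholesky factor is available), and squashes with a
sigmoid.  Putting the 1/f scale in the render rather than only in the
initialization preconditions the gradient, which is the point of the
parameterization.  The adjoint of the inverse FFT is implemented explicitly
(weighted rfft with real-only coupling at the DC/Nyquist columns) and
validated against finite differences.  Initial spectra are white Gaussian
draws (sd 0.1 — a visibly noised start; near-gray inits leave many trained
ReLU channels with exactly zero gradient) projected onto the subspace of
valid real-field transforms so render/transform round-trips are exact.
Ascent is Adam at lr 0.05 for 512 steps by default, with no regularization
terms; a constant (zero-gradient) objective returns the initial render with
a warning.  Selectors can target the pre-ReLU activation (`pre_relu=True`),
the standard way to visualize units that are dead at the init.

**Semantic dictionary.**  Defined strictly at the GAP layer, where
conservation Σₖcₖ + bⱼ = logitⱼ holds exactly and is asserted at 1e-5 on
every image.  Ranking uses the element-wise mean contribution over the
supplied image set (ties broken by neuron index); `top_n` defaults to 6.
GAP-neuron renders target the GAP-input feature layer (the identical
objective) at pre-ReLU.

**Attention maps.**  All maps are min-max normalized to [0, 1] with
constant maps collapsed to zero; raw signed values are retained for
quantitative work.  Coarse maps are bilinearly upsampled to input
resolution.  Choices where the methods are under-specified:

* occlusion: 32×32 mask, stride 16, mask value 0.5 (≈ dataset mean) by
  default; overlapping drops are averaged, not maximized; scores are
  pre-softmax logits.  Cost contract: exactly (#positions + 1) network
  evaluations.
* superpixel surrogate: SLIC segmentation (or a user-supplied label
  image); binary on/off designs are enumerated exhaustively when
  2^#segments fits the sample budget, otherwise sampled; plain least
  squares with an intercept, ridge damping (λ=1e-3) only on singular
  designs.  Exactly n_samples evaluations.
* gradient maps aggregate channels by max |·| (the saliency-map
  convention).
* integrated gradients use the midpoint rule α=(k−½)/steps from a black
  baseline; completeness error is < 1 % of F(x)−F(x⁰) at 128 steps on the
  fixture and shrinks as steps double.
* Grad-CAM weights are spatial means of ∂logit/∂activation; at the last
  feature layer of a GAP-head network it coincides with class activation
  mapping (cosine > 0.999, asserted).  A guided-gradient variant is
  offered, since "Grad-CAM with a guided ReLU" admits two readings; the
  default is vanilla.
* explanation map: thresholds are mean reference activations *per neuron*
  — per spatial position and channel — so the healthy references act as a
  positional control and shared structure cancels; the per-channel spatial
  mean is available as `threshold_mode="channel"`.  Channels are rectified
  against their threshold, ranked by spatial sum, and the top 3 summed.
  Forward-only by construction (asserted via the backward-call counter).

## Evaluation and shaving

Sensitivity is heat *mass* on the lesion over total heat mass — no
binarization threshold to pick; IoU at τ=0.5 and the pointing game are
reported alongside.  The misclassification report tabulates top-m
predictions with attention maps and a background-attention fraction (heat
mass outside the leaf), which a constructed background-confound experiment
shows is higher for misclassified than for correctly classified images.

`shave_series` freezes copied feature layers by default and trains only the
fresh head — the cheaper, reproducible reading of transfer learning (a
fine-tune-all flag exists).  Head-only training is a logistic fit on frozen
GAP features, so the default budget (30 epochs, lr 0.02, batch 32) is sized
for convergence of that fit; parameter totals are checked to increase
strictly with cut depth.

## Problem sizes

The test suite and the acceptance script run the synthetic task at 160
images (40 per class, 64×64), a 3-conv-block fixture CNN, 20 diseased test
images for map evaluation, 128-step feature-visualization renders over all
channels of the three blocks, and full-scale (224×224, 38-class)
architecture construction for the exact parameter accounting — the
package's chosen desk-scale conditions.

## Known limitations

* The engine is CPU/numpy: fine for 64×64 fixtures and for building and
  counting the full-scale graph; training the full InceptionV3-like model
  on real data is out of scope.
* Rescale-rule conservation is exact only on affine+ReLU graphs (max
  pooling is gradient-routed).
* The explanation map's "neuron" thresholds assume spatially aligned
  imagery (single centered leaf); unaligned datasets should use
  `threshold_mode="channel"`.
* Unregularized activation maximization can produce adversarial-looking
  textures; renders are evidence of what excites a unit, not of what the
  unit detects in natural images.
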