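# Methods

## Problem and model

The package estimates the nutrient composition of a dish from a single RGB
photograph.  The output is a probability vector over seven classes —
protein, fat, fiber, carbohydrate, minerals, water, and an explicit
*remainder* class — interpreted as fractions of a nutrient reference value
(NRV%/100).  The remainder class exists because the tracked nutrients of a
real food do not sum to 100% of the reference intake; adding it lets a
softmax simplex represent the tracked values faithfully and makes the
output of every stage a proper distribution.

The network has four stages.

**Environment feature extraction (EFE).**  The input image is converted to
the HSI color space: with chromaticities r = R/(R+G+B) (likewise g, b),

    h = arccos( 0.5·((r−g)+(r−b)) / sqrt((r−g)² + (r−b)(g−b)) ),
    h ← 2π − h  when b > g,
    s = 1 − 3·min(r,g,b),      i = (R+G+B)/(3·255),

scaled to H ∈ [0,360), S ∈ [0,100], I ∈ [0,255].  Degenerate pixels are
handled by convention: achromatic pixels (the arccos argument is 0/0) get
H = 0, and the black pixel maps to (0,0,0).  The guard is applied only
where the hue denominator vanishes so that non-degenerate pixels are
computed exactly.  Inside the network the three planes are rescaled to
[0,1] so they are numerically comparable.

The HSI planes pass through a per-pixel linear projection (a 1×1
convolution to an embedding width), parallel convolutions with different
kernel sizes (same padding, so all branches and the module output preserve
the spatial grid), channel concatenation, a 1×1 convolution, the MDN
normalization described next, and a final 1×1 convolution.  No pointwise
nonlinearity is inserted between these stages; MDN itself is the module's
nonlinearity, and GELU appears in the encoder and decoder.

**MDN (distribution-partition normalization).**  Feature planes (channels)
are grouped by distributional similarity and each group is divided by the
Euclidean norm of all its elements.  Per-plane value histograms (32 bins)
are compared by KL divergence, KL(P‖Q) = Σ P(x) ln(P(x)/Q(x)), after
additive smoothing (1e−8) so disjoint supports stay finite.  For the
default two partitions the reference distributions are the histograms of
the planes with the highest and lowest mean absolute activation — a proxy
for the subject/background contrast the layer is meant to separate; for
K > 2 the references are K-medoids under KL with a deterministic,
rank-spread initialization.  Two binning conventions coexist deliberately:
the public histogram routine bins over a plane's own min–max range (its
stated contract), while partitioning bins all planes over the shared
tensor-wide range, because plane-local ranges erase location information
and would make two constant planes of different value indistinguishable.
The assignment is recomputed every forward pass and treated as
non-differentiable routing; the division by the partition norm is smooth
and receives the exact gradient d(x/l)/dx = g/l − x·(x·g)/l³.  Zero-norm
partitions pass through unchanged.

**Dual-attention encoder.**  The EFE output grid is average-pooled by a
token-pool factor and flattened to a token matrix X (tokens are rows).
Each layer computes a local triple Q = X·Wq, K = X·Wk, V = X·Wv and a
separately parameterized global triple, forms the focused attention
C = softmax(QKᵀ/√d_k)·V and the independent attention I (same form, global
parameters), and fuses them as Wo·(αC + βI) with learnable scalars α, β
initialized at 0.5 (learnable subsumes fixed; β = 0 recovers a standard
single-path layer).  Multiple heads replicate the C/I machinery on d/n_head
slices with concatenation before Wo; n_heads = 1 reproduces the single-head
formulas verbatim.  Residual connections, post-layer normalization and a
GELU feed-forward sublayer (width 4d) follow standard transformer practice.
After the attention stack an ASPP block (parallel 3×3 dilated convolutions
plus a 1×1 branch, fused by 1×1 convolution) aggregates multi-scale
context, and the original image — bilinearly resized to the encoder grid
and 1×1-projected to the feature width — is added as a residual, giving the
encoder direct access to raw local appearance.

**Decoder with token sleeping.**  The decoder attends over the token set
with the same scaled-dot-product form.  During training a supervision layer
maintains, per token, the mean absolute post-attention activation over a
sliding window of W optimization steps.  Once the window is full, tokens
whose statistic falls strictly below a threshold tau are put to sleep for a
fixed number of epochs: a sleeping token is excluded from the attention
matmul (shrinking it) and its output row is the activation row frozen at
sleep entry; counters decrement at epoch boundaries, re-flagging an asleep
token does not extend its sleep, and tau = 0 disables the mechanism exactly
(strict inequality).  Sleeping is treated as a training-time mechanism;
evaluation always uses the full token set, which keeps inference
deterministic.  The decoder body is attention → dropout → layer
normalization → fully connected residual blocks (GELU) → mean pooling over
awake tokens → a linear map to the feature vector.

**Nutrient head.**  Fully connected → GELU → dropout → fully connected →
softmax.  GELU is x·Φ(x) with Φ the exact standard-normal CDF (erf-based,
not the tanh approximation).

## Objective and metrics

Training minimizes the weighted mean absolute error

    WMAE = (1/Σ w_i) · Σ w_i · |y_pred,i − y_true,i|

with strictly positive per-nutrient weights (uniform by default; the
weights exist to prioritize nutrients of interest).  The |·| subgradient at
0 is taken as 0.  Optimization is Adam (lr 1e−3 default), fully seeded:
data order, initialization, dropout and sleep events are reproducible bit
for bit.

Evaluation uses regression-style accuracies: for the class with the largest
predicted probability, TOP1 = max(0, 1 − |Xp − Xr|/Xr) where Xp is the
predicted and Xr the reference content of that class; TOP5 averages the
same clamped score over the five most probable classes.  The clamp
implements the zero-score rule — a nutrient predicted absent (or off by
more than 100% relative) scores 0 — without which the score could go
negative.  Background robustness is measured as the population variance,
per nutrient class, of predictions for one foreground rendered over
different backgrounds; smaller is better.

## Synthetic data

The generator renders elliptical "dishes" whose appearance encodes the
latent nutrient vector by a linear rule published in the code: with
u = food/(n_foods−1), dish hue is 300u degrees and encodes the carbohydrate
fraction 0.10 + 0.40u, and the sinusoidal texture frequency 2 + 3u cycles
encodes the protein fraction 0.30 − 0.22u; fat is 0.04 + 0.06u, fiber and
minerals are constant, and water/remainder split the rest 70/30.  All seven
fractions are strictly positive and the food → nutrients map is injective,
so the regression task is identifiable.  Dishes are composited over
interchangeable background clutter (solid, gradient, checkerboard, noise);
the foreground is a deterministic function of (food, seed) only, never of
the background, which is what makes the background-stability ablation
well-posed.  The default fixture uses 6 foods at a 64×64 native render.

What the generator does *not* emulate: real food photography's lighting
variation, occlusion, mixed dishes, perspective, camera noise, or any
nonlinear appearance–composition relationship.  Passing the recovery tests
therefore shows that the architecture, objective and training loop are
implemented correctly and can extract a visually encoded composition
signal; it does not certify accuracy on real food images.

## Scaling and numerical choices

- The model runs at a configurable working resolution (default 32×32;
  the compact test configuration uses 16×16) obtained by bilinear
  resampling of the 224×224 preprocessed input, and the encoder pools the
  EFE grid by `token_pool` before flattening, keeping the attention token
  count at 64.  This keeps the quadratic attention cost tractable on a
  single CPU while preserving every architectural element.
- The compact configuration (`ModelConfig.small()`): kernel sizes {1,3,5},
  embedding 8, 24→32 channels, one encoder layer with 4 heads, ASPP rates
  {1,2,3}, two decoder FC blocks, ~6·10⁴ parameters, float32 arithmetic.
  The full default keeps kernel set {1,3,5,7} and ASPP rates {1,6,12,18}.
- Experiments in the test suite use 500 training / 100 held-out images and
  30 epochs for recovery, and 200 training images, 10 epochs and 20
  background pairs per arm for the stability ablation, repeated over three
  seeds with a majority rule — sizes chosen as the smallest at which the
  effects are reliably visible.
- Resizing uses pixel-center-aligned bilinear interpolation (the skimage/
  PIL convention).  Rotation augmentation fills out-of-frame pixels by
  reflection to avoid injecting artificial black background.
- The softmax subtracts the (detached) row maximum — exact by shift
  invariance.  The arccos argument in the HSI conversion is clamped to
  [−1,1] against floating-point overshoot.  Histogram bin edges follow the
  half-open convention with the maximum folded into the last bin.
  Ties in KL assignment break toward the lower partition index.
- Gradient correctness is verified against central finite differences in
  float64 for every autodiff primitive and for the WMAE objective through
  the nutrient head (1e−4 relative, away from the |·| kink).

## Design choices where the design was open

- "Inactive neurons" are operationalized at token granularity; per-unit
  sleeping inside the FC layers is out of scope.  Inactivity statistic,
  window (50 steps), tau (1e−3) and sleep length (2 epochs) are all
  configurable defaults.
- The per-pixel linear projection reads "mapping the image to one
  dimension" as a pointwise channel projection — a literal flatten would
  destroy the spatial structure the convolutions need.
- The model predicts simplex proportions; NRV%-style output is the same
  vector scaled by 100 (shown by the CLI `predict` table).
- HSI may replace the RGB input (default) or be concatenated with it
  (`hsi_mode: concat`).
- The plain-stem ablation arm (3×3 → 3×3 → 1×1 convolutions on raw RGB,
  hidden width chosen to match the EFE parameter count) isolates the
  contribution of the HSI front end, the multi-scale branches and MDN
  jointly.

## Known limitations

- No GPU path; the numpy implementation is single-threaded apart from BLAS.
- Sleeping at evaluation time is not implemented (no speed-up claim at
  inference is made or tested).
- The synthetic appearance–composition link is linear and noise-free; real
  nutrient estimation requires training on real paired data.
- Checkpoints store raw weights keyed by module path; there is no
  cross-version migration.
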