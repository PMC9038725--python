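# Methods

## The model

`darunet` implements a two-stage attention-gated residual U-Net for
binary segmentation of 2-D grayscale medical images. Two structurally
identical networks are chained. NET1 maps the input image X to a
salient probability map X1 = NET1(X). NET2 receives the element-wise
product X1 ⊙ X — the input re-weighted by where NET1 believes the
structure is — and produces the final map X2. During decoding, NET2
concatenates the attention-gate outputs of *both* networks at each
scale, so the two networks are coupled twice: through the product at
the input and through the shared skip content. Gradients from the final
loss therefore reach every parameter of both networks.

Each network consists of:

- **Encoder** — five blocks of `conv 5×5, stride 2, same padding` →
  batch norm → leaky ReLU (slope 0.2), with 20/40/80/160/320 filters
  (full width). Each block halves the spatial dimensions, so inputs
  must be divisible by 2⁵ = 32; `data.pad_to_multiple` handles that.
- **Residual bottleneck** — four blocks computing `x + F(x)` with
  `F = BN∘conv∘BN∘conv` (5×5, stride 1, 320 filters). There is no
  nonlinearity after the second convolution, so zeroing the branch
  makes the block an exact identity — the property that lets gradients
  bypass the bottleneck.
- **Attention gates** — at each decoder scale, the skip features x are
  re-weighted by a single-channel coefficient map
  `α = σ(ψ(ReLU(W_x x + W_g up2(g) + b_g)) + b_ψ) ∈ (0,1)`,
  where g is the immediately coarser decoder (or bottleneck) feature,
  upsampled ×2 (bilinear by default, nearest selectable), and W_x, W_g,
  ψ are 1×1 convolutions. α broadcasts across channels:
  `gated = x ⊙ α`.
- **Decoder** — four blocks of `transposed conv 5×5, stride 2`
  (160/80/40/20 filters) → batch norm → dropout 0.3 (training only) →
  concatenation with the gated skip(s) → ReLU.
- **Output head** — a final transposed conv 5×5 stride 2 to one channel
  with sigmoid activation, restoring the input resolution.

Weights are initialised from N(0, 0.02²); biases start at zero. Batch
normalisation uses momentum 0.99 and ε = 1e−3, with running statistics
for inference.

### Training objective

The loss is minus the soft Dice coefficient,

    soft_dice(p, t) = (2 Σ p·t + ε) / (Σ p + Σ t + ε),   ε = 1e−6,

optionally plus an auxiliary minus-Dice term on NET1's output weighted
by λ (default 0.5, a light deep-supervision signal for the salient
map; λ = 0 trains on the final output alone). The loss lives in
[−(1+λ), 0] and reaches its minimum at perfect overlap. Optimisation
is Adam (lr 1e−4, β₁ 0.9, β₂ 0.999, ε 1e−7) at batch size 1, with a
per-epoch reshuffle drawn from the run seed.

### Numerical engine

No GPU framework is used: the package ships a small reverse-mode
autodiff engine over NumPy arrays (NHWC layout) implementing exactly
the operations the architecture needs — strided same-padded
convolution (im2col), transposed convolution (as the adjoint of the
matching strided convolution), batch normalisation, bilinear/nearest
×2 upsampling, dropout, concatenation and the pointwise
nonlinearities. Every operation's backward pass is verified against
central finite differences in the test suite. Arrays are float64
throughout; checkpoint round-trips are bit-exact.

## Design choices where the design was open

- **Level counts.** Both networks use 5 encoder blocks, 4 decoder
  blocks and 1 transposed-conv output head. This is the only
  arrangement consistent with the filter lists (20…320 encoding,
  160…20 decoding) and with the stride arithmetic that returns the
  input resolution; it is recorded in `NetworkConfig` so alternatives
  remain expressible.
- **Gate resampling direction.** The gating signal g is upsampled ×2
  to the skip resolution (rather than downsampling x), which keeps α
  at skip resolution and makes the concatenation shapes line up.
- **α dimensionality.** ψ produces one feature map; α is
  single-channel and broadcast across the skip channels.
- **Deepest gating signal.** The residual-stack output gates the
  deepest attention gate; each shallower gate is gated by the previous
  decoder block's output.
- **F_int.** The gates' intermediate width is F_l/2 (minimum 1) per
  scale, configurable via `NetworkConfig.attention_intermediate`.
- **Residual branch.** `F = BN∘conv∘BN∘conv` with no intermediate
  ReLU, matching the identity-when-zeroed contract exactly.
- **Standard deviation in standardisation.** Per-image population SD
  (so a two-pixel image standardises to ±1), guarded at 1e−8 so
  constant images map to zeros. Standardisation is applied after
  resizing and before padding; the zero pad equals the standardized
  background mean.
- **Binarisation.** Probability ≥ 0.5 → foreground (ties go to
  foreground); the rule is idempotent.
- **Empty-mask conventions.** DSC/JSC are 1.0 when both masks are
  empty and 0.0 when exactly one is; the Hausdorff distance and the
  Feret length are reported as undefined (never zero) when a contour
  is empty, and undefined values are excluded from aggregates and
  counted.
- **Contours.** 4-neighbour boundary (foreground pixels with a
  4-neighbour background pixel or on the image border) — the thinnest
  standard boundary.
- **Length.** Maximum Feret diameter (largest pairwise distance
  between contour points) of the largest 8-connected component, in
  pixels or mm when a pixel spacing accompanies the sample.
- **Bland–Altman.** Bias ± 1.96·SD with the n−1 SD — standard
  normal-theory limits. Box-whisker quartiles use linear interpolation
  between order statistics with Tukey 1.5·IQR fences.

## Synthetic phantoms

`darunet.synthetic` generates the benchmark the tests and the
acceptance script train on: one connected, randomly deformed ellipse
(random centre, axes, rotation; radius modulated by a few smooth
harmonics) whose area fraction is rejection-sampled into a configured
window (default 8–30% of the frame), rendered as a bright structure
(0.75) on a darker background (0.35), attenuated linearly top-to-bottom
(30%), multiplied by unit-mean Gamma speckle (shape k = 4, a standard
fully-developed-speckle surrogate) and Gaussian-blurred (σ = 1 px).
Default canvas is 64×64 for fast experiments; any size works.

What this emulates: a bright, soft-edged, low-contrast lesion on a
textured background with multiplicative noise — the statistical
character of clinical ultrasound frames. What it does not: acoustic
shadowing, anisotropic point-spread, real anatomy, annotation noise, or
multi-structure scenes. Passing the desk-scale tests therefore shows
the architecture, losses, gradients and pipeline are correct and that
the model can fit this signal; it says nothing about clinical
segmentation accuracy, which requires the real datasets and full-scale
training.

## Problem sizes

The package's standard desk-scale experiment — used by the test suite
and `scripts/acceptance.py` — trains the reduced-width configuration
(encoder 4/8/16/32/64, decoder 32/16/8/4, ≈2.0 M parameters) on eight
64×64 phantoms for 200 epochs at batch size 1, which takes a few
minutes on one CPU core and reaches a training-set Dice near 0.99. The
full-width model (≈49.2 M parameters) is exercised for its shape,
parameter-count and gradient contracts on 480×320 inputs, not trained.

## Known limitations

- CPU-only and single-threaded beyond BLAS; full-width training at
  clinical resolution is out of reach of this engine by design.
- Batch size is fixed at 1 (as in the published protocol); batch norm
  in training mode therefore normalises per-image.
- Binary (single-foreground) segmentation only; no 3-D volumes, no
  DICOM/NIfTI readers, no data augmentation.
- The Hausdorff distance is in pixels unless the manifest provides a
  mm/px spacing.
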