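# Methods

## Model

The segmentation network is a five-stage encoder–decoder for binary
per-pixel classification of 2-D images (RGB or grayscale). Stages 1–3
are residual convolution blocks; stages 4–5 are tokenized-MLP blocks
operating on the 16×- and 32×-downsampled grid. The design follows the
convolution-for-texture / MLP-for-context split: cheap convolutions
handle high-resolution local structure, and token MLPs with axial
channel shifts model the coarse layout where the grid is small enough
that fully connected mixing is affordable.

Conventions fixed where the design was genuinely open:

- **Tokenization.** The learned tokenizer is a 3×3 overlapped patch
  embedding (windowed linear map); it is applied once at each tokenized
  stage entry with stride 2, which produces the stated ×2 resolution
  reduction and sets the channel count to the embedding dimension E.
  *Inside* a block, tokens are the plain row-major flattening of the
  grid (equivalently the same windowed map with a centred identity
  kernel). A learned stride-1 3×3 map per pass was considered and
  rejected: it adds ≈9E² parameters and ≈9E² MACs per token per pass,
  which moves essentially all of the block's cost out of the embedding
  dimension and into dense convolutions — the opposite of the block's
  stated purpose — and roughly doubles the whole network's compute.
- **Shifts.** Channels are split into n = 5 partitions shifted by
  (−2, −1, 0, 1, 2) along the chosen axis, vacated positions zero-filled;
  a channel remainder joins the last partition. The public
  `axial_shift` rejects |offset| ≥ extent; inside the network, offsets
  are clamped (sign preserved) to the grid extent so the model stays
  total on small inputs whose bottleneck grid is 2×2.
- **Block activation** f = GELU, the activation used throughout the
  architecture, computed exactly as x·Φ(x) via the error function.
- **Positional encoding** = the depthwise 3×3 convolution applied to the
  width-pass MLP output; `use_pe=False` removes exactly that layer.
- **Residual token stream.** The height-pass residual adds the
  stage-entry tokens (the block input), then layer-normalises
  (eps 1e-6).
- **Shortcuts and skips.** Conv blocks use an identity shortcut when
  channels match and a learned 1×1 projection otherwise. Encoder→decoder
  skip connections are element-wise additions (keeping parameter counts
  low); concatenation is available as `skip_mode="concat"`, in which
  case the join happens after each decoder stage's block so channel
  widths remain well-defined.
- **Token-MLP hidden width** `mlp_ratio` = 1.0 (hidden = E).
- **Upsampling** is corner-aligned bilinear interpolation: the source
  position of output index i is i·(n_in−1)/(n_out−1), so u = v = 0
  reproduces source pixels exactly and each output is the four-neighbour
  weighted sum. The same routine resizes images in the data pipeline.
- **Initialisation.** Truncated normal (std 0.02, ±2σ) for token MLPs,
  Kaiming-normal for convolutions, LN/BN scale 1 and shift 0, all from
  one seeded generator per model.
- Dropout is not modelled: no rate is specified for this architecture
  family and the overfit-style tests require none.

The implementation, including reverse-mode differentiation, is pure
NumPy (`rmisnet.autodiff`); gradient correctness is established by
central finite differences over every layer type.

## Loss and metrics

`L = w·BCE + (1 − Dice)` with w = 0.5 and Dice
`(2Σŷy + ε)/(Σŷ + Σy + ε)`, ε = 1.0 by default ("smooth" Dice);
probabilities are clamped to [1e-7, 1 − 1e-7] before the BCE
logarithms. The Dice *similarity* itself is sometimes written added to
the loss in this family's descriptions; only the 1 − Dice form yields a
coherent training objective and is what is implemented. BCE is the mean
over pixels; the Dice term pools the whole batch.

Metrics (accuracy, precision, recall, F1, IoU) come from per-pixel
confusion counts with foreground = positive; zero-denominator cases
return 0. Per-image-then-average is the default aggregation, pooled
counting is available — which of the two a published table used is
generally not stated, so both are provided. F1 = 2·IoU/(1 + IoU) holds
exactly on counts and is property-tested.

## Profiler

Parameters: exact count of trainable scalars. MACs: closed per-layer
forms summed over one forward pass — k×k convolution
Cout·Cin·k²·Hout·Wout, depthwise C·k²·H·W, token MLP tokens·in·out;
pooling, normalisation, activations, shifts and bilinear upsampling are
excluded. "GFLOPs" means giga-MACs (one multiply–add counted once), the
convention under which lightweight segmentation networks report
sub-1 GFLOP figures at 256²; `flops=True` doubles the count. Counting is
independent of weight values and train/eval mode, and is verified in the
tests against per-layer sums derived by hand.

### Residual discrepancy against previously reported profiles

Published structural figures for this family (6.74 / 3.68 / 1.42 M
parameters and 1.84 / 0.76 / 0.24 GFLOPs for channel configurations
scaling as c, 2c, 4c) are mutually inconsistent with *any* fixed
architecture: every layer's size is a polynomial of degree ≤ 2 in a
common channel scale, and fitting K + Ac + Bc² through either printed
triple forces a negative coefficient (B < 0 for the parameter triple,
K < 0 for the GFLOP triple). No resolution of the open design choices
(tokenizer form, `mlp_ratio`, positional-encoding form) can therefore
reproduce all printed values; calibrating `mlp_ratio` can match at most
one of them and was not done. This package keeps the principled
defaults above and reports its own exact counts:

| configuration | params (M) | GFLOPs @256² |
|---|---|---|
| full (16,32,64,128,256) | 1.01 | 0.74 |
| full (32,64,128,256,512) | 4.00 | 2.90 |
| full (8,16,32,64,128) | 0.25 | 0.19 |
| conv stages only | 0.88 | 0.85 |
| tok-MLP without PE | 1.00 | 0.74 |

The default configuration's compute (0.74 G) lands at the reported
0.76 G scale; the parameter totals do not match the published column,
and the published 0.03 M cost of the positional encoding exceeds what
depthwise 3×3 kernels can account for at any of these widths (ours is
≈0.006 M).

## Data pipeline

Images load channel-first in [0, 1] (8- or 16-bit); masks binarise as
value > 0. Resizing: corner-aligned bilinear for images, the matching
nearest-index map for masks (preserves binarity). Augmentation applies
horizontal flip, rotation and "cutting" each independently with
probability 0.20 to training pairs, with identical geometry on image and
mask: rotation draws from ±30° with reflect padding (no angle is
standard; ±30 keeps blobs in frame), and cutting is a random crop to 0.8
of each side followed by resize back. Masks use order-0 resampling and
are re-binarised, so image/mask alignment is exact for flip and crop and
≥0.99 IoU for rotation (edge interpolation). Splitting is a uniform
seeded permutation; explicit per-split counts take precedence over
fractions because published counts are not exact fractions of the
totals.

## Training

Adam with β₁ = 0.9 (the "momentum" of this family's training setups is
read as the first-moment coefficient), β₂ = 0.999; learning rate from
the per-epoch cosine schedule with lr_max = 1e-4, lr_min = 0 and
T_max = max_epochs = 500 by default. Early stopping uses strict decrease
of the validation loss with tolerance 1e-6 and patience 2; the
best-epoch weights are restored and checkpointed (weights + exact config
+ BN running statistics; save→load→forward is bit-identical).
Prediction thresholds the logistic probability at 0.5, ties to
background.

## Synthetic fixtures and problem sizes

The generator emulates the relevant statistics of nuclei/lesion data:
bright, roughly round foreground blobs (1–6 disks of radius 4–12 px,
intensity 0.65–0.95 with a soft radial profile) on a noisy dark
background (level 0.15, Gaussian σ = 0.08), mildly blurred, with the
mask the *exact* analytic disk union — so ground truth carries no
annotation noise. Every sample is a pure function of (seed, index). It
does not emulate instance contacts, staining variation, hair/ruler
artefacts or annotation ambiguity, so passing tests demonstrate the
correctness of the machinery, not clinical-grade accuracy on real
micrographs or dermoscopy.

Demonstration problem sizes are chosen for a single CPU: the overfit
check trains channels (8,16,32,64,128) on sixteen 64×64 blob images
with lr_max = 1e-3 (a standard quick-overfit rate for Adam; the 1e-4
default pairs with full-scale 500-epoch runs), batch 8, T_max = 200,
patience disabled for the demo, stopping once training Dice reaches
0.95. It converges in ≈50 epochs. Reproducing published accuracy on the
real competition datasets is out of scope: it requires the external
data and GPU-scale training.

## Known limitations

- Binary foreground only; no multi-class head, no 3-D volumes.
- The NumPy backend is single-process and CPU-bound; it is meant for
  desk-scale verification, not large-scale training.
- BN statistics come from small batches in the demos; eval-mode
  predictions early in training can lag the train-mode loss.
- Wall-clock inference timing is deliberately not reported: it is
  hardware-bound and outside the profiler's analytic scope.
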