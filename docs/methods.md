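# Methods

This note documents the models, algorithms, parameters and design choices
behind `virtualher2`, and what the synthetic study conditions do and do not
establish.

## 1. Staining network

**Generator.** Attention-gated U-Net, 4 resolution levels. Each
down-sampling block is a two-convolution residual block (two 3×3
convolutions with a 1×1 convolutional residual path), a LeakyReLU of slope
0.1, and a 2×2 max pool of stride 2. Per-level in/out channels are
(4, 64, 128, 256) → (64, 128, 256, 512). A center residual block maps
512 → 1024. Each up-sampling block bilinearly upsamples the running tensor
2× (half-pixel-aligned interpolation), gates the matching encoder skip with
an attention gate, concatenates, and applies a residual block; the nominal
per-level in/out channels are (1024, 1024, 512, 256) → (1024, 512, 256,
128), where the listed *input* width counts the upsampled running tensor
and the concatenated skip adds its own width on top (so the first up-block
convolves 1024 + 512 channels down to 1024). A final residual block at 128
channels and a single 3×3 convolution produce the 3-channel RGB output.
The output is linear; values are clipped to [0, 1] only at export. There is
no normalization layer anywhere, and all convolutions carry biases.

**Attention gate.** Three convolutions and a sigmoid: 1×1 projections of
the skip tensor and the gating signal to half the skip width, summed,
ReLU, 1×1 convolution to one channel, sigmoid; the resulting [0, 1] map
multiplies the skip tensor.

**Discriminator.** 3×3 convolution + LeakyReLU to 64 channels, then five
two-convolution residual blocks that each double the channel count and
halve the spatial dimensions (stride 2 on the second convolution and on
the residual path), global average pooling, and two fully connected layers
(hidden width 512 — a conventional choice, config-exposed) to one logit.

**Losses.** Generator: `α·SmoothL1 − λ·log((1+SSIM)/2) + γ·BCE(D(G(x)),1)`
with (α, λ, γ) = (10, 0.2, 0.5); discriminator: `BCE(D(G(x)),0) +
BCE(D(y),1)`. SmoothL1 uses β = 1 (quadratic 0.5d²/β below β, linear
beyond). The SSIM in the objective uses *global* per-image statistics
(population variances), exactly as the formula is written; an 11×11
Gaussian sliding-window mode (σ = 1.5, delegated to scikit-image with
matching constants) is used for evaluation reporting, where windowed SSIM
is the community convention. The SSIM constants are c1 = 0.01² = 1e-4 and
c2 = 0.03² = 9e-4 on a [0, 1] dynamic range — the standard constants; both
are config entries. BCE is evaluated in the log-sum-exp form and is stable
for |logit| up to at least 1e4.

**Autodiff engine.** The networks run on a purpose-built numpy
reverse-mode engine (`virtualher2.nn`): broadcast arithmetic, GEMM-based
convolutions (im2col in channel-last layout; 1×1 convolutions reduce to a
plain matrix product), 2×2 max pooling with first-match tie-breaking,
factor-2 bilinear upsampling as a pair of sparse interpolation matrices,
and AdamW. Gradients of every primitive are tested against central finite
differences. Weights are He-normal, seeded; float32 is the working
precision (losses evaluate in float64 when given float64 arrays, which is
how the 1e-10 oracle comparisons are run).

## 2. Training protocol

Splits are patient-disjoint at ~80/10/10 by tile count; a patient's tiles
never straddle splits. Crops are drawn uniformly from the tile pair at
identical positions (optional joint flip/rot90 augmentation, off by
default). One *step* is one optimizer update; the 2:1
generator:discriminator frequency is realized as the repeating schedule
G, G, D (the generator-favoring reading, consistent with the weak γ = 0.5
adversarial weight). The discriminator trains on the detached output of
the immediately preceding generator step. AdamW uses lr 1e-4 (G) and 1e-5
(D), weight decay 1e-5 (unstated in the protocol; a conventional small
value), β = (0.9, 0.999). Validation MSE is computed on full validation
tiles — not crops — through the same channel normalization as training,
and the checkpoint with the lowest validation MSE is selected (ties →
earliest step). AF channels are normalized per channel to the (0.1, 99.9)
percentile range of the training tiles; the normalizer travels with the
fitted results so inference sees training statistics.

Desk-scale study conditions (used by the test suite): generator and
discriminator channel widths divided by 8, 208 synthetic pairs of 96×96 px
(52 per grade, 4 tiles per synthetic patient), 64-px crops, batch 8,
2000 steps (1334 G + 666 D), checkpoints every 500 steps. The learning
rates scale with the model: 1e-3 (G) / 1e-4 (D), preserving the full-scale
protocol's 10:1 ratio — at 1e-4 the reduced generator cannot even memorize
a single tile within the desk-scale step budget (an optimization-speed
effect, not a capacity limit). The acceptance
script runs a slightly smaller study (160 pairs, 1200 steps) so the whole
pipeline fits one short CPU run; both are seeded and deterministic.

## 3. Registration workflow

1. **Global alignment** — ORB keypoints and binary descriptors on a
   representative channel per modality (AF DAPI vs. inverted brightfield
   luminance), cross-checked matching, RANSAC similarity estimation
   (residual threshold 2 px); RMS residual over inliers is reported.
   Fewer than 3 inliers raises a registration failure (unusable slide).
   The detector is pluggable; ORB was chosen as the available
   blob-with-descriptor detector in scikit-image.
2. **Tiling** — the aligned WSIs are cut on a regular grid (1024 px at
   full scale) into co-located tile pairs; border partials are dropped.
3. **Pyramid elastic registration** — 3 levels (×4, ×2, ×1 downsampling).
   The block size is fixed in level coordinates (default 48 px, i.e. a
   192-px physical extent at the coarsest level shrinking to 48 px at full
   resolution) so fine levels can follow short-period deformations; blocks
   overlap 50 %. Each block shift is the subpixel peak (1-D parabola
   refinement per axis) of the normalized cross-correlation between the
   reference block and the moving block's interior, searched within ±10 px;
   flat or weakly correlated blocks (peak < 0.2) are imputed from their
   nearest valid neighbor. Block displacements are linearly interpolated
   to a dense field, Gaussian-smoothed with σ = block/6, scaled to full
   resolution, and composed with the running field (proper pull-back
   composition). Fields are pull-back maps: `out(r, c) = src(r + dy,
   c + dx)`, 0-based (row, col), pixel-centered.
4. **Iterated refinement** — up to 5 rounds of: refresh the style bridge
   on the current pairs, elastic-register each brightfield target to its
   bridge output, apply the field. The default bridge is a pixel-wise
   linear regression of target optical density on the four AF channels,
   rendered through Beer–Lambert (fast, and its fit sharpens as alignment
   improves, which is what drives the residual down across rounds); a
   generator-architecture bridge that is fine-tuned between rounds is also
   provided. The loop stops when the median residual displacement of the
   last round's field drops below tolerance (0.5 px default), and halts
   flagged if the residual grows on two consecutive rounds. A final
   cleaning pass flags pairs with bridge–target NCC < 0.5 or tissue
   fraction < 10 % as not clean — an automated proxy for manual curation,
   with thresholds in config.

On synthetic composite warps (translation up to 12 px plus sinusoidal
elastic deformation up to 6 px, period ≥ 96 px) the recovered field's mean
endpoint error is below 1 px; the block size and smoothing were fixed from
this synthetic oracle.

## 4. Synthetic study conditions

Each tile draws a latent tissue map: cell centers by dart throwing
(minimum spacing 17 px, density 0.0022 cells/px²), nucleus radii uniform
in 4–7 px, per-cell hematoxylin density uniform in 0.55–0.80, a smooth
stroma field, and membrane rings in an annulus 1 px outside the nucleus,
2 px thick. The per-grade membrane ladder is:

| grade | complete rings | partial rings | arc fraction | DAB density |
|-------|----------------|---------------|--------------|-------------|
| 0     | 0 %            | 0 %           | —            | 0           |
| 1+    | 0 %            | 45 %          | 0.15–0.50    | 0.15        |
| 2+    | 35 %           | 20 %          | 0.50–0.90    | 0.35        |
| 3+    | 60 %           | 15 %          | 0.50–0.90    | 0.90        |

Ring counts are deterministic rounded fractions of the cell count, so the
"complete membranous staining in >10 % of cells" property of positive
grades holds by construction. Per-cell DAB density varies ×U(0.8, 1.2).

The IHC image is Beer–Lambert transmission `rgb = 10^(−OD)` with the
standard hematoxylin (0.650, 0.704, 0.286) and DAB (0.269, 0.568, 0.778)
unit optical-density vectors (third basis vector = normalized cross
product). Each AF channel is a fixed nonlinear mix (power-law γ = 0.8) of
the latent density maps — DAPI dominated by nuclei, TxRed/Cy5 carrying the
membrane signal, FITC mostly stroma — plus additive Gaussian noise
σ = 0.02 (a Poisson option exists, off by default; the AF noise model is
otherwise unconstrained). Because membrane *density* enters the AF mix,
the HER2 grade is in principle recoverable from the AF stack, which is the
property the mapping-recovery study tests.

What the generator does **not** emulate: real tissue texture and
morphological heterogeneity, staining artifacts, tissue tearing and
out-of-focus regions, scanner color profiles, and the cross-modality
appearance gap of real AF imagery. Passing the desk-scale tests therefore
shows the pipeline is implemented correctly and can learn a well-posed
AF→IHC mapping — not that it reaches clinical image quality on patient
data.

## 5. Quantification

Color deconvolution uses OD = −log10(max(rgb, 1e-6)) and densities
OD·M⁻¹, negatives clipped. Nucleus statistics: Otsu threshold on the
hematoxylin density (a constant channel raises an explicit degenerate-
threshold error), morphological opening with a radius-2 disk, removal of
components < 30 px, 8-connected labeling. The membrane characteristic
curve re-renders the DAB density alone to RGB, converts to HSV, and sweeps
the saturation threshold s over 0.10…0.50 in steps of 0.02 (21 points);
its AUC is the trapezoidal integral, and connectedness is the largest
8-connected component fraction at s = 0.25. PSNR uses peak 1.0 and is
capped at 100 dB for identical images. Color histograms are normalized by
total pixel count and smoothed with a reflected-boundary Gaussian kernel
(bandwidth 0.05 OD), which preserves unit mass.

## 6. Reader-study statistics

Confusion matrices are 4×4 (rows = assigned, columns = reference). The
weighted off-diagonal error is Σ count·|assigned − reference| over
off-diagonal cells — the only summary consistent with a diagonal/error
pair like (19, 18) on 36 evaluations, since 36 − 19 = 17 ≠ 18.
The chi-square comparison is two-sided Pearson without continuity
correction; because the original contingency construction is not
specified, the layout is a pluggable policy (default: 2×4 modality ×
assigned-score table; a concordant/discordant 2×2 is also provided, and an
explicit table bypasses the policy). Zero-margin categories are collapsed
and a flag reports expected counts below 5. Paired quality t-tests form
d = virtual − IHC per ROI and test mean d < 0 one-sided ("is the chemical
stain better?"); membrane-clearness pairs with a missing grade
(HER2-negative tissue) are dropped; all-zero differences return p = 0.5 by
convention and constant nonzero differences return the degenerate limit
p ∈ {0, 1} with an infinite statistic. Significance is 0.05.

The bundled reader-study table (`datasets.synthetic_reader_study`) is a
synthetic stand-in — the real score sheets are private clinical data —
constructed with 36 evaluations per modality, predominantly adjacent
errors, diagonal sums 22 (virtual) / 19 (IHC) and weighted errors 14 / 18,
matching the summary profile of the blinded study this harness emulates.
The stats module always computes summaries from the long-form table; it
never hard-codes them.

## 7. Known limitations

* The autodiff engine is single-threaded numpy; full-scale (channel-
  undivided) training is intentionally out of scope — only architecture
  conformance is exercised at full width.
* Elastic registration assumes locally translational block motion; strong
  rotations inside a tile would need the affine stage to absorb them.
* The chi-square p-value depends on the chosen contingency layout and is
  therefore reported, not asserted, on the synthetic table.
* Windowed SSIM on the DAB channel uses the [0, 1] data-range convention
  although optical densities can exceed 1; this matches how the metric is
  reported but compresses very strong stains.
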