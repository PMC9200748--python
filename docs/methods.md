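# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices that are not forced by the problem, and what the
test suite does and does not demonstrate.

## The translation model

The generator is a U-Net mapping a 3-plane brightfield z-stack to the five
fluorescent Cell Painting channels, both standardized per image and per
channel to mean 0 / sd 1. Six encoder blocks (32, 64, …, 1024 filters),
two 3×3 stride-1 "same" convolutions per block, each followed by ReLU then
batch normalization; 2×2 max-pooling between blocks; a symmetric decoder
with 2×2 stride-2 transposed convolutions and skip concatenations; a final
1×1 convolution with no activation or normalization. Two convolutions per
block is the classic U-Net choice and is what brings the default
architecture to ≈31.1 million trainable parameters; the parameter-count
test pins that choice. "Same" padding (1 px on 3×3 kernels) is forced by
the requirement that output size equals input size, unlike the
valid-padding original U-Net.

Input sides must be divisible by 2^(levels−1) = 32; full fields are
handled by tiled inference instead (patch 256, stride 128, per-pixel
median of the covering patches). When the stride grid does not land on the
far edge — 998 px being the working example, since 998 − 256 = 742 is not
a multiple of 128 — the final row/column of tile origins is clamped to the
edge, narrowing the overlap band there. Edge and corner pixels are covered
by fewer than four patches; the median is taken over however many cover
the pixel, with an even count resolved as the mean of the two middle order
statistics. Stitching patches of the ground truth reproduces it bit
exactly, which the suite asserts for 256, 512 and 998 px.

## Adversarial training

The cWGAN-GP regime keeps the generator and adds a conditional Wasserstein
patch critic over the 8-channel concatenation of brightfield and
fluorescent stacks: three 4×4 stride-2 convolutions (16 → 32 → 64
filters), then a 1×1 projection to a spatial score map; the scalar score
is the map's mean. WGAN critics must be unbounded, so there is no sigmoid,
and the per-patch "classification" view of a patch discriminator becomes a
per-patch score that is reduced by averaging.

Objectives, with λ₁ = 100, λ₂ = 10 and λe = 1/epoch (1-based, so the first
epoch has weight 1 and the adversarial pull halves with each doubling of
the epoch index):

* generator minimizes λ₁·L_L1 − λe·E[D(x, G(x))];
* critic minimizes −(E[D(x, y)] − E[D(x, G(x))]) + λ₂·L_GP, i.e. it
  maximizes the real−fake score gap while being penalized for input
  gradients away from unit norm. The gradient penalty uses the squared
  form (‖∇_x̂ D‖₂ − 1)², one uniform interpolate per sample, with the
  critic score summed over the batch before differentiation so each
  sample's gradient is batch-size independent. A linear-critic closed form
  (unit-gradient ⇒ penalty 0; constant critic ⇒ penalty 1) and a
  finite-difference comparison pin the implementation.

Training schedules follow the reference regime: L1 phase with Adam
(lr 2·10⁻⁴, weight decay 2·10⁻⁴), batch 10, 50 epochs — 15,000 iterations
at 3000 training wells; adversarial phase with Adam (lr 2·10⁻⁴,
β = (0, 0.9), critic weight decay 10⁻³), batch 4, 28 epochs — 21,000
critic iterations, with one generator step per five critic steps (the
generator reuses every fifth batch rather than consuming extra ones, so
n batches yield n critic and n/5 generator updates). No data
augmentation. The deployed checkpoint is the epoch with the best mean
validation PCC, ties to the earlier epoch; the validation split defaults
to a random 10%.

Choices the sources leave open, made here and exposed in configuration:
critic activation (LeakyReLU 0.2, the standard patch-critic choice), no
normalization layers in the critic (normalization interacts poorly with a
per-sample gradient penalty), critic padding 1 and mean reduction of the
score map, and mean-PCC as the epoch-selection metric.

## The autodiff engine

No deep-learning framework is a dependency; `brightstain.nn` is a small
reverse-mode autodiff engine on numpy. Convolution is composed from
`unfold` (im2col) → matrix product → reshape, and every primitive's
backward rule is itself written with the same primitives, so gradients of
gradients — required by the penalty term's weight gradients — come out of
the same machinery and are verified against central finite differences
(layers to ~1e-10 relative in float64; the double-backward path to 1e-5).
Parameters are float32; Adam follows the usual L2-coupled weight-decay
convention so published learning rates transfer.

## Synthetic paired microscopy

The generator renders fields with a known brightfield → fluorescence
relationship so that learning is possible and its limits are known:

* **Scene**: non-overlapping elliptical cells (semi-major axis 10–14 px,
  rejection-sampled placement) with elliptical nuclei at 45% scale.
* **Fluorescence**: DNA = nuclei with smooth chromatin texture;
  ER = cytoplasm modulated by a σ = 3 px random texture; RNA = faint
  cytoplasm plus 2–3 bright nucleolar spots per nucleus (σ ≈ 1 px);
  AGP = a 2-px membrane rim plus 1-px filament chords; Mito = Poisson
  puncta (σ = 0.7 px, density 0.03 px⁻²) in the cytoplasmic ring.
* **Brightfield**: three channel-mixtures of the scene structures, blurred
  with plane-specific σ = (2, 1, 3) px for (z−4, z0, z+4) — information
  loss grows away from focus, which is why a z-stack carries more than any
  single plane — plus additive Gaussian noise (default sd 0.02).
* **Perturbations**: positive-control scenes enlarge cell area by
  30%·effect and divide Mito puncta density by (1 + effect), a
  mitoxantrone-like cytostatic phenotype; batches multiply fluorescent
  intensities by a per-batch factor (default +30% for batch B — the
  magnitude of real batch effects is not well characterized, so it is a
  configuration parameter).

Raw images are written as 16-bit TIFFs scaled to use ~[0, 20000] of the
range, mimicking how real acquisitions sit well below the theoretical
maximum; per-image standardization in preprocessing then removes the
batch-level intensity scale, exactly as it does for real data.

The fine AGP/Mito structure is rendered at 1–2 px precisely so the
σ ≥ 1 px brightfield blur destroys part of it: those channels are
*designed* to be the hardest to predict, which gives the pipeline the same
difficulty ordering seen with real fine subcellular structure. A linear
regression from the three planes to DNA reaches pixel PCC ≈ 0.75 (the
suite requires > 0.5), so training smoke tests are meaningful rather than
vacuous.

What the generator does **not** emulate: optical physics, spectral
bleed-through, stain chemistry, cell-to-cell contact morphology, plate
spatial effects, or realistic texture statistics. Passing tests therefore
show the machinery is correct and the mapping learnable — they do not
certify performance on real microscopy.

## Evaluation

Image metrics are computed per channel on standardized images: MAE, MSE,
Pearson correlation of flattened pixels (zero-variance input is an error,
not a silent 0), PSNR on 8-bit conversions, and SSIM. Two conventions are
not fixed by the metric names and are chosen here: PSNR's 8-bit conversion
uses a single affine map from the min/max of the union of the two images,
which preserves relative error and keeps PSNR symmetric (identical images
report infinity); SSIM uses a 7×7 uniform window, stabilizers
C1 = (0.01·L)² and C2 = (0.03·L)² with L the dynamic range of the pair,
and averages fully interior windows — cross-checked against an independent
reference implementation to 1e-6. Metrics default to the standardized
(model-space) images; this is configurable.

Morphological profiling accepts external CellProfiler-style tables and
also ships a stand-in extractor (per compartment × channel: mean and
integrated intensity, area, difference-of-blur granularity, local-variance
texture, neighbour counts, concentric-ring radial distribution) whose
point is schema compatibility, not CellProfiler's formulas. Profiles are
median-aggregated per well; feature selection applies, in order: (1) drop
features with > 5% missing or > 5% zero values — the "zeros" reading of an
ambiguous rule, threshold configurable; (2) drop blocklisted names;
(3) greedy decorrelation at |r| > 0.9, scanning features by decreasing
variance so the more informative member of a correlated pair survives;
(4) drop features with SD > 15 over negative-control wells, computed on
raw values with global (not per-plate) statistics. Selection is computed
on ground-truth profiles only and applied unchanged to every model source,
so the survivor set cannot favour a model. Predicted-vs-truth agreement is
per-feature Spearman (midranks for ties; zero-variance features excluded)
averaged within (compartment, channel, feature type) groups; embeddings
use UMAP (n_neighbors 15, min_dist 0.8, 2 components, seeded) with PCA as
the confirmatory alternative.

Toxicity calling z-scores the profiles per feature (zero-variance → 0),
then runs a K-NN classifier (k = 5, Euclidean) 100 times, each run drawing
max(#pos, #neg) control profiles per class with replacement; the final
call is the majority over runs, with an exact 50/50 tie called non-toxic
(the specificity-preserving default). Control wells are scored
leave-self-out — a well's own resampled copies are excluded from its
neighbour set — since otherwise each control trivially votes for itself
and specificity is inflated. The K-NN is implemented directly on a
precomputed distance matrix because that exclusion does not fit a stock
classifier interface.

## Problem sizes and numerical notes

The scaled-down learning check trains a levels = 4 / base 16 U-Net
(≈0.48 M parameters) on 200 synthetic 128-px fields (noise sd 0.01) with
64-px random crops, batch 8, Adam lr 10⁻³, 12 epochs — sizes chosen so the
whole pipeline, including this run, executes comfortably on a single CPU
while still reaching mean held-out PCC ≥ 0.8 with the fine-structure
channel worst. Gradient-norm computations add 10⁻¹² inside the square root
to avoid a non-differentiable point at zero; training aborts with a
diagnostic (and, in the adversarial loop, restores the last stable
checkpoint) if any loss goes non-finite. Patch sampling truncates the
patch size down to the generator's divisibility constraint. 16-bit export
rounds to nearest so that save → load → save is bit-stable.

## Known limitations

* The engine is CPU-bound numpy: the full 31 M-parameter generator is for
  architecture introspection and small-scale inference, not for training
  at the reference scale.
* The stand-in feature extractor is a schema-compatible proxy; absolute
  feature values are not comparable to CellProfiler's.
* Synthetic batch effects are a single multiplicative intensity factor;
  real batch variation is richer.
* UMAP coordinates are seeded but remain sensitive to library version;
  tests assert geometry (cluster separation), not coordinates.
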