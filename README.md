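# brightstain

Label-free Cell Painting: predicting the five fluorescent Cell Painting
channels — DNA, ER, RNA, AGP (actin/Golgi/plasma membrane) and Mito
(mitochondria) — from a 3-plane transmitted-light brightfield z-stack
(in focus, ±4 µm), and evaluating how useful those predictions are for
morphological profiling.

The package is aimed at image-analysis groups in phenotypic drug discovery
who want to know whether a generative model can stand in for fluorescent
staining: it implements the full loop from paired microscopy data to
downstream toxicity calls, and ships a synthetic paired-microscopy
generator so that every stage runs, end to end, without any proprietary
dataset.

## The model

Two training regimes share one generator, a 6-level U-Net `G` with
3 input / 5 output channels, 32 → 1024 filters (doubling per level), two
3×3 convolutions per block each followed by ReLU and batch normalization,
2×2 max-pooling on the way down, 2×2 stride-2 transposed convolutions with
skip concatenation on the way up, and a linear output convolution — about
31 million trainable parameters.

1. **U-Net / L1** minimizes the pixel reconstruction loss
   `L_L1 = E[ ||y − G(x)||₁ ]`.
2. **cWGAN-GP** continues from the L1-trained generator and adds a
   conditional Wasserstein patch critic `D(x, ·)` over the 8-channel
   (brightfield, fluorescent) concatenation:

   ```
   generator:  L_G = λ₁·L_L1 − λe·E[D(x, G(x))],      λ₁ = 100, λe = 1/epoch
   critic:     min −(E[D(x,y)] − E[D(x,G(x))]) + λ₂·L_GP,   λ₂ = 10
   L_GP = E[(‖∇_x̂ D(x, x̂)‖₂ − 1)²],   x̂ uniform on segments between real and fake
   ```

   with 5 critic updates per generator update, Adam (lr 2·10⁻⁴,
   β = (0, 0.9)), batch 4.

Inference runs in 256×256 patches with stride 128 and reconstructs each
pixel as the median of the overlapping patch predictions. Evaluation is
three-tiered: image metrics (MAE, MSE, SSIM, PSNR, PCC) per channel;
feature-level Spearman correlation of morphological profiles grouped by
compartment × channel × feature type; and profile-level toxicity calling
with a balanced-resample K-NN (k = 5, 100 runs, majority vote) trained on
control wells.

Because no deep-learning framework is part of the dependency stack, the
networks run on a small reverse-mode autodiff engine (`brightstain.nn`)
written on numpy, with compositional primitives so the gradient penalty's
second-order gradients are exact (finite-difference-tested).

## Worked example

```python
from brightstain import (VirtualStainingModel, TrainingConfig, GeneratorConfig,
                         SceneSpec, generate_field, preprocess)

fields = [preprocess(generate_field(SceneSpec(image_size=128, n_cells=10,
                                              noise_sd=0.01, seed=s)))
          for s in range(100)]
model = VirtualStainingModel(fields, TrainingConfig(patch_size=64, seed=0),
                             GeneratorConfig(levels=4, base_filters=16))
results = model.fit("l1", epochs=8, batch=8, lr=1e-3)
print(results.summary())
```

prints (about one minute of CPU):

```
VirtualStainingModel results (U-Net / L1)
==========================================================
fields: 100   trainable parameters: 483,509
epochs run: 8   best epoch (mean val PCC): 8

validation metrics at best epoch (per channel):
         MAE     MSE    SSIM     PSNR     PCC
DNA   0.1184  0.1651  0.8795  25.8137  0.9371
ER    0.2414  0.2665  0.7281  21.6843  0.9120
RNA   0.1612  0.3979  0.8991  28.6848  0.8086
AGP   0.2868  0.5590  0.6048  18.0092  0.8442
Mito  0.2172  0.7409  0.7809  26.3614  0.5864

channel means: MAE=0.2050  MSE=0.4259  SSIM=0.7785  PSNR=24.1107  PCC=0.8176
```

Reading it: on held-out synthetic fields the network recovers the nuclear
(DNA) and reticular (ER) channels almost perfectly (PCC ≈ 0.91–0.94), while
Mito — whose 1–2 px granular puncta are mostly erased from the blurred
brightfield planes by construction — is the hardest channel (PCC ≈ 0.59).
That difficulty ordering, coarse structure easy / fine structure hard, is
the qualitative signature this pipeline is designed to surface.

A command-line interface chains the full synthetic pipeline:

```
brightstain all --out runs/desk --seed 1
```

writing a per-channel metric table, grouped feature correlations and a
toxicity call table under `runs/desk/`.

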