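# virtualher2

Label-free **virtual HER2 immunohistochemistry** at desk scale: a complete,
self-contained implementation of a deep-learning virtual staining pipeline
that transforms 4-channel autofluorescence (AF) images of unlabeled breast
tissue sections (DAPI, FITC, TxRed, Cy5 filter analogues) into brightfield
images equivalent to chemically performed HER2 IHC staining — together with
the registration workflow that builds pixel-accurate training pairs, the
feature-based HER2 stain quantification, and the blinded-reader-study
statistics used to judge such a system.

The package is aimed at computational-pathology researchers who want a
reproducible, dependency-light reference of the full method: every stage is
exercised end to end on a seeded synthetic tissue generator, so no patient
data or GPU is required.

## The model

The staining network is a conditional GAN. The generator G is an
attention-gated U-Net with 4 resolution levels (channel plan
4, 64, 128, 256 → 64, 128, 256, 512 down; 1024, 1024, 512, 256 →
1024, 512, 256, 128 up) mapping the AF stack I_input to an RGB estimate of
the IHC image I_target; the discriminator D is a residual CNN (five
two-convolution blocks, each downsampling 2×) ending in a single logit.
They are trained alternately (two generator updates per discriminator
update; AdamW, lr 1e-4 / 1e-5, batch 28 at full scale) on the losses

```
l_generator     = α·SmoothL1(I_target, G(I_input))
                  − λ·log[(1 + SSIM(I_target, G(I_input))) / 2]
                  + γ·BCE(D(G(I_input)), 1),      (α, λ, γ) = (10, 0.2, 0.5)
l_discriminator = BCE(D(G(I_input)), 0) + BCE(D(I_target), 1)
```

with SmoothL1 the β = 1 Huber-style distance, SSIM the global-statistics
structural similarity (c1 = 1e-4, c2 = 9e-4), and BCE the numerically
stable binary cross-entropy on logits. The networks are implemented on a
small numpy reverse-mode autodiff engine (`virtualher2.nn`) written for
this package and verified against finite differences.

Around the network the package provides:

* `synth` — seeded synthetic paired tiles: latent tissue maps (nuclei,
  grade-dependent membrane rings, stroma) rendered to AF stacks and, via
  Beer–Lambert transmission of hematoxylin/DAB optical densities, to IHC
  brightfield images; plus parametric warps for registration ground truth.
* `register` — ORB keypoints + RANSAC global similarity alignment, 1024-px
  tile pairing, style-bridge-assisted pyramid elastic registration
  (block-wise normalized cross-correlation, coarse to fine), and the
  iterated train–register refinement loop with automated pair cleaning.
* `train` — patient-disjoint 80/10/10 splitting, random co-located crop
  sampling, and the statsmodels-style `VirtualStainingModel.fit()` →
  `VirtualStainingResults` pair (checkpoints, loss histories, batch
  manifests, `summary()`, `stain()`).
* `stain` — overlapped tile inference with cosine-feather stitching.
* `metrics` — color deconvolution (hematoxylin/DAB), nucleus count and
  area via Otsu + morphology, the membrane characteristic curve (stained
  area fraction vs. HSV-saturation threshold s = 0.10…0.50, step 0.02),
  its AUC, membrane connectedness at s = 0.25, PSNR / windowed SSIM /
  SSIM_DAB, and smoothed per-stain color histograms.
* `stats` — ROI sampling harness, 4×4 confusion matrices with diagonal and
  weighted off-diagonal summaries, two-sided chi-square modality
  comparison, and one-sided paired t-tests on 1–4 quality grades.

## Worked example

```python
import numpy as np
from virtualher2 import synth, metrics, stats
from virtualher2.datasets import synthetic_reader_study

# --- reader-study arithmetic on a blinded HER2 score table -------------
table = synthetic_reader_study()
for modality in ("virtual", "ihc"):
    m = stats.build_confusion(table, modality)
    diag, weighted = stats.confusion_summaries(m)
    print(modality, "diagonal sum:", diag, " weighted off-diagonal error:", weighted)

# --- membrane quantification of one synthetic 3+ tile ------------------
pair = synth.simulate_pair(3, seed=1)
sep = metrics.separate_stains(pair.ihc)
curve = metrics.membrane_stats(sep)
nuc = metrics.nucleus_stats(sep)
print("nuclei:", nuc.count, " membrane AUC:", round(curve.auc, 4),
      " connectedness:", round(curve.connectedness, 4))
```

prints

```
virtual diagonal sum: 22  weighted off-diagonal error: 14
ihc diagonal sum: 19  weighted off-diagonal error: 18
nuclei: 132  membrane AUC: 0.0532  connectedness: 0.0074
```

The confusion summaries say that of 36 blinded whole-slide evaluations per
modality, 22 virtual-stain reads matched the reference HER2 score (vs. 19
for standard IHC), and the total ordinal distance of the misreads was 14
(vs. 18) — virtual staining scored no worse than the chemical stain. The
membrane AUC integrates stained-area fraction over the saturation
threshold sweep and rises with HER2 grade; connectedness is the largest
connected stained component as a fraction of the field of view.

Training a reduced desk-scale model end to end:

```python
from virtualher2 import VirtualStainingModel, TrainConfig, GeneratorConfig, DiscriminatorConfig
pairs = synth.simulate_dataset(52, geometry=synth.GeometryParams(96, 96))
model = VirtualStainingModel(
    pairs, gen_cfg=GeneratorConfig().reduced(8), disc_cfg=DiscriminatorConfig().reduced(8),
    train_cfg=TrainConfig(crop=64, batch=8, max_steps=2000))
results = model.fit()
print(results.summary())
virtual_rgb = results.stain(pairs[0].af)   # (96, 96, 3) brightfield estimate
```

A command-line interface mirrors the pipeline:
`virtualher2 simulate|register|train|stain|evaluate|stats --help`.

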