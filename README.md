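# vhucsnet

Dual-track kidney-mass segmentation for 2-D image slices: a
**transformer-enhanced U-Net** segments the organ, a **contrast-optimized
protuberance detection network (PDN)** segments the mass from the
organ-masked image, and a deterministic fusion overlays the two into one
labeled raster (0 background, 1 organ, 2 mass) with the mass constrained
inside the organ.

The package is aimed at researchers who want a CPU-runnable, fully
reproducible reference implementation of this dual-track design — including
preprocessing, paired augmentation, dataset splitting, training, metrics and
a synthetic phantom generator — without any external dataset or GPU.

## The model in brief

Track 1 encodes the image with a patch embedding (stride-P convolution +
learned positional table) and four stages of ViT attention
(`ViT(F) = MHSA(LN(F)) + F`, then `FFN(LN(·)) + ·`) followed by HRNet
multi-scale convolutions (`F_HR = Σ_s W_s * F_ViT`, kernels {1,3,5}), with
stride-2 max pooling between stages: 224²×3 → 112²×64 → 56²×128 → 28²×256 →
14²×512. A convolution+ReLU bridge lifts the deepest stage to 14²×1024 and
an additive-skip decoder (1×1-projected encoder feature + transposed-conv
upsampling) reconstructs a 224²×64 feature map, reduced by a 1×1
convolution + sigmoid to the organ probability map S_k.

Track 2 receives `I_PDN = I ⊙ M̂` — the preprocessed image gated by the
*predicted* organ mask (never ground truth) — and runs a conv/BN/ReLU stem,
a multiscale ladder of [max pool → widening conv → Δ] with the
centre–surround contrast `Δ(x) = x − boxmean₃ₓ₃(x)` (256² → 16²×1024), a
depthwise-separable/BN/LeakyReLU border refinement (16²×512), concat fusion
(16²×1536), and a 1×1 conv + sigmoid + threshold head for the mass mask S_m.
The final output is the fused overlay Φ(S_k, S_m).

Both tracks train sequentially with Adam on the soft Dice loss
`L = 1 − (2|P·G|+ε)/(|P|+|G|+ε)`; evaluation reports Dice, IoU
(D = 2J/(1+J)), HD95 and ASSD as mean ± SD [95% CI].

The networks run on a small numpy reverse-mode autodiff engine included in
the package (`vhucsnet.autodiff` / `vhucsnet.layers`), gradient-checked
against finite differences in the test suite.

## Worked example

No data is needed — the phantom generator stands in for the kidney-slice
dataset. The canonical desk-scale run (64×64 phantoms, widths divided by 4,
200 train / 40 test, 10 epochs, Adam lr 1e-3, batch 16) takes about two
minutes on one CPU core:

```python
from vhucsnet.experiments import desk_experiment

res = desk_experiment(seed=0)
for name, rep in res.reports.items():
    m, sd, lo, hi = rep.aggregates()["dice"]
    print(f"{name:5s} Dice {m:.4f} +/- {sd:.4f} [{lo:.4f}-{hi:.4f}]")
print(f"PDN-alone mass Dice {res.pdn_alone_mass_dice:.4f}")
```

prints

```
organ Dice 0.9705 +/- 0.0065 [0.9579-0.9832]
mass  Dice 0.6798 +/- 0.1475 [0.3907-0.9688]
PDN-alone mass Dice 0.6596
```

The organ track segments the elliptical organ almost perfectly (Dice 0.97
against held-out phantoms); the mass track localizes the protruding disc
(Dice 0.68 — lower because the mass is small and the PDN's probability grid
is coarse); and the fused mass Dice is *above* the raw PDN value because
fusion deletes the PDN's out-of-organ false positives.

The same pipeline is available from the shell:

```bash
vhucsnet generate --out data --n 240 --size 64 --seed 0
vhucsnet train --data data --out run --epochs 10 --seed 0
vhucsnet predict --images data/images --checkpoints run --out pred
vhucsnet evaluate --data data --checkpoints run --out eval
```

`train` writes `organ.npz` / `mass.npz` checkpoints, per-sample metric CSVs
and a JSON summary; `predict` writes labeled masks plus color overlays
(organ contour in green, mass filled red).

## Library surface

* `vhucsnet.estimators` — `OrganSegmenter`, `MassDetector`,
  `DualTrackSegmenter`: scikit-learn-style estimators
  (fit/predict/predict_proba/get_params) over image arrays.
* `vhucsnet.phantom` — deterministic organ-with-mass phantom generator.
* `vhucsnet.data_io` — PNG pair loading, the 80/10/10 split rule
  (`floor` on train, proportional remainder), CSV manifests, a NIfTI
  slice adapter.
* `vhucsnet.preprocess` / `vhucsnet.augment` — CLAHE + histogram
  equalization, mask passthrough, masked-image construction; paired
  flips/rotation/brightness-contrast/elastic augmentation.
* `vhucsnet.metrics` — Dice, Dice loss, IoU, HD95, ASSD, confusion counts,
  mean ± SD [95% CI] aggregation.
* `vhucsnet.vhu_net` / `vhucsnet.cond_pdn` / `vhucsnet.fusion` — the two
  networks and the label fusion.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

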