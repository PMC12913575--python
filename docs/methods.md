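# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `vhucsnet`.

## Problem and approach

Kidney-mass segmentation from 2-D slices is treated as two coupled binary
segmentation problems. Track 1 segments the organ from the full image;
Track 2 segments the mass from the *organ-masked* image, i.e. the
preprocessed image multiplied element-wise by the organ mask that Track 1
predicted. Gating the mass track on predictions (never on ground truth)
keeps the inference path free of annotation leakage. A deterministic
fusion overlays the two masks into a three-label raster — background 0,
organ 1, mass 2 — and suppresses mass pixels that fall outside the organ,
so the containment `mass ⊆ organ` holds in every output.

## Track 1: transformer-enhanced U-Net

The encoder tokenizes the image with a non-overlapping patch embedding
(stride-P convolution, P = 2 by default, plus a learned additive positional
table) and runs four stages of

    ViT block  →  HRNet block  →  (stride-2 max pool before the next stage)

* **ViT block**: layer norm → multi-head self-attention → residual add,
  then layer norm → two-layer feed-forward (expansion 2, ReLU) → residual
  add. Heads default to 4. Self-attention is quadratic in token count, so
  above a configurable token limit (4096 at full scale) the block attends
  on an average-pooled token grid (factor 4) and broadcasts the attention
  output back before the residual add; the pointwise feed-forward half
  always runs at full resolution. A log message flags whenever the pooled
  path is active.
* **HRNet block**: a sum of parallel same-padded convolutions at kernel
  scales {1, 3, 5}, then batch norm and ReLU. The parallel-scale sum is
  what preserves fine spatial structure alongside the attention pathway.

With a 224×224×3 input and widths 64→128→256→512 the stage outputs are
112²×64, 56²×128, 28²×256 and 14²×512. A 3×3 convolution + ReLU bridge
lifts the deepest feature to 14²×1024. The decoder runs four stages of

    1×1-project the matching encoder skip → add → ×2 transposed-conv
    upsample → 3×3 convolution + ReLU

consuming the skips deep-to-shallow (512, 256, 128, 64 channels) at
exactly matching resolutions and ending at 224²×64; a 1×1 convolution +
sigmoid yields the organ probability map. We add the skip *before*
upsampling (rather than after) because that is the unique ordering in
which all four encoder features align with the decoder resolutions.

Two width presets exist side by side, reflecting two configurations that
are both sensible: the wide one above (default, matching the printed
feature-map shapes) and a narrow one obtained with `width_divisor=4`
(widths 16→128, bridge 256).

## Track 2: contrast-optimized protuberance detection network (PDN)

A stem (3×3 convolution + batch norm + ReLU) lifts the masked image to the
first stage width. Each of the following stages applies

    stride-2 max pool → widening 3×3 convolution + batch norm + ReLU →
    Δ contrast

where the contrast operator is the centre–surround difference
`Δ(x) = x − boxmean₃ₓ₃(x)`. The box mean normalizes by the number of
in-image pixels of the window, so Δ annihilates spatially constant maps
*exactly*, including at the borders. At full scale four stages shrink a
256² input to a 16²×1024 contrast map. A depthwise-separable convolution
(depthwise 3×3, pointwise 1×1 to 512 channels) + batch norm + LeakyReLU
(slope 0.01) produces the border-refined map; the two branches are
concatenated (1024 + 512 = 1536 channels), reduced by a 1×1 convolution +
sigmoid to a one-channel probability grid, bilinearly upsampled to the
output size, and thresholded strictly above τ (default 0.5 — a constant
0.5 map therefore yields an empty mask, a deterministic tie rule).

The head bias is initialized at −2: masses cover only a few per cent of
the frame, and starting the sigmoid near that prior removes the early
plateau of the Dice loss. Per-stage batch normalization in the widening
ladder serves the same purpose; both choices were made on phantom
validation curves during development.

## Preprocessing and augmentation

Images are enhanced by CLAHE (clip limit 2.0 on the conventional integer
scale, i.e. 2/256 after scikit-image's normalization; 8×8 tile grid)
followed by global histogram equalization; both are monotone intensity
maps. Multi-channel images are enhanced on their luminance with channels
rescaled proportionally. Masks are never contrast-processed — only
nearest-neighbour resizing.

Training-time augmentation applies one identical spatial map to image
(bilinear) and mask (nearest neighbour): horizontal/vertical flips
(p = 0.5 each), rotation within ±20° (p = 0.5; a 15° alternative is
config-exposed), and an elastic deformation (p = 0.3) built from a
Gaussian-smoothed random displacement field (alpha 1, sigma 50) plus a
3-point affine jitter (alpha_affine 50), resampled with reflective
borders. Brightness/contrast jitter (p = 0.3, ±0.2 fractional limits —
the limits are our choice, config-exposed) touches the image only.
Contrast enhancement is applied deterministically on the inference path;
augmentation is training-only.

## Training

Both tracks minimize the ε-smoothed soft Dice loss (ε = 1e-6) with Adam.
The published configuration is learning rate 1e-3 (a 1e-4 preset also
exists), batch 32, 35 epochs; the desk preset below uses batch 16. The
two tracks train sequentially: the organ track first, then the mass track
on images masked by the *trained* organ track's predictions — the only
ordering consistent with the gating definition. Checkpoint selection is
by best validation Dice over a 10% holdout of the training set. One seed
drives weight initialization, shuffling and augmentation, so a fixed seed
reproduces a run bitwise. `Dice loss = 1 − soft Dice`: every published
(loss, dice) pair satisfies this complement exactly, which is why the
loss is implemented as a complement rather than a negation.

## Evaluation

Dice and IoU use ε-smoothed pixel counts (both-empty pairs score 1.0 by
the smoothing; this is documented behaviour, not an error). HD95 and ASSD
are computed on 4-connectivity erosion-residue boundaries with Euclidean
distances (via a distance transform), optionally scaled by a pixel
spacing; empty masks are refused, with an opt-in 0.0 sentinel for
identical-empty pairs. Aggregates are mean ± population SD with a fixed
1.96 normal multiplier for the 95% interval — exactly the arithmetic of
the published tables. SD can be taken across test samples (the default
per-report aggregation) or across seeds by aggregating per-seed means.

## Synthetic phantoms

Each phantom is an elliptical organ (semi-axes 14–22 × 11–18 px on a
64×64 frame, random centre near the middle, random orientation) with a
disc-shaped mass (radius 5–9 px) centred *on the organ contour* so it
protrudes — matching the protuberance the mass track is specialized for;
an interior-mass mode exists for ablations. The organ mask is the union
of ellipse and disc, so mass ⊆ organ by construction. Intensities are
piecewise constant (background 30, organ 110, mass 190) plus a smooth
Gaussian texture field (SD 5) and iid Gaussian noise (SD 8), clipped to
[0, 255] and quantized to 8 bits so PNG round-trips are bit-exact. Each
sample is fully determined by (seed, index).

What the phantoms do *not* emulate: CT physics, anatomical shape
variability, neighbouring organs, partial-volume effects, or multiple
masses. Passing the phantom experiments therefore demonstrates that the
architecture, training loop and fusion logic work end to end and that the
mass track genuinely learns from contrast cues — not that clinical-grade
accuracy would transfer to real CT data.

## Desk-scale experiment

The canonical CPU run uses 64×64 single-channel phantoms, `width_divisor
4` (organ track ≈ 0.91 M parameters, mass track ≈ 0.21 M), 200 training /
40 test samples, 10 epochs, Adam lr 1e-3, batch 16. Two further
desk-preset choices: the organ track pools attention above 256 tokens
(the 32² first-stage grid attends at 8×8), and the mass track uses three
pooling stages instead of four, leaving an 8×8 probability grid. The
latter preserves a workable mass-to-grid ratio: projecting ground-truth
masses onto a 4×4 grid caps the achievable mass Dice at ≈ 0.62 regardless
of training, while an 8×8 grid caps it at ≈ 0.91. Problem sizes were
chosen so the full dual-track run completes in roughly two minutes on one
CPU core.

## Numerical choices

* All network arithmetic is float32; the autodiff engine is gradient-
  checked against central finite differences in the test suite.
* Sigmoid outputs are clamped to [1e-7, 1 − 1e-7] so probability maps stay
  strictly inside (0, 1) under float32 saturation and the Dice loss keeps
  a gradient.
* Max-pool backward breaks ties deterministically toward the first
  maximum in each window.
* The split rule `train = floor(n·(1 − r_val − r_test))`, with the
  remainder divided proportionally (floor on validation, rest to test),
  reproduces the published partition counts exactly; the floor is guarded
  against float representation of exact integers.
* The transposed convolution is restricted to kernel = stride (the exact
  ×2 upsampling the decoder uses).

## Known limitations

* Attention above the token limit is a pooled approximation, not full
  self-attention; it is flagged in logs whenever active.
* Parameter counts of the full-scale models are reported by the package
  (`count_parameters`, checkpoint summaries) but are not expected to
  match any externally published totals, which are not recoverable from
  their description.
* The boundary-metrics sentinel for empty masks is a pragmatic choice;
  comparisons involving empty predictions should be read with care.
* No DICOM input, no 3-D volumes (a NIfTI slicer adapter is provided),
  no test-time augmentation, no learned fusion.
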