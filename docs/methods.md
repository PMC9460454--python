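# Methods

## The model

SEMD is a DeepLabV3+ encoder–decoder for binary standing-tree segmentation
whose backbone is MobileNetV2 modified in two ways: the classification tail
(the final 1×1 convolution to 1280 channels and the global average pool) is
removed, and the resulting 320-channel feature map is recalibrated by a
squeeze-and-excitation (SE) block followed by an extra 3×3 convolution to
512 channels for high-dimensional feature extraction.

**Backbone.** The stem is a 3×3 stride-2 convolution to 32 channels; seven
inverted-residual stages follow with (expansion t, channels c, repeats n,
stride s) = (1,16,1,1), (6,24,2,2), (6,32,3,2), (6,64,4,2), (6,96,3,1),
(6,160,3,2), (6,320,1,1). Every inverted residual expands with a 1×1
convolution (×t), filters with a 3×3 depthwise convolution, and projects
back linearly, with an identity skip when stride is 1 and channel counts
match. Activations are ReLU6 = min(max(0, x), 6). All convolutions are
bias-free and followed by batch normalization. The depthwise-separable
factorization costs C2 = K²·M·F_H·F_W + M·N·F_H·F_W multiply-accumulates
against C1 = K²·M·N·F_H·F_W for a standard convolution — a ratio of
1/N + 1/K² — with parameter counts P2 = K²·M + M·N versus P1 = K²·M·N.
`semd.backbone.conv_cost` implements these closed forms, and the test suite
checks them against counts enumerated from instantiated layers.

**SE block.** Squeeze: global average pool each channel to a scalar.
Excite: s = σ(W2·ReLU(W1·z)) with a bottleneck of width C/r; we use r = 4
(a quarter of the channel count), which trades a little capacity for a
smaller, faster block. Reweight: multiply channel c by s_c ∈ (0, 1). One SE
block is applied to the final 320-channel map (before the extra 3×3×512
convolution); a per-block SE variant exists behind a constructor flag but
is off by default, since the structure table adds SE once behind the
backbone. The SE→conv order was a genuinely open choice; we place SE first
so the attention operates on the bottleneck features the tables describe.

**Encoder/decoder.** ASPP runs a 1×1 branch, 3×3 atrous branches at rates
(6, 12, 18) for output stride 16 (doubled at output stride 8), and a
global-average-pool branch, each to 256 channels, concatenated and fused
1×1. The decoder projects the 24-channel stride-4 backbone tap to 48
channels, upsamples the fused map bilinearly to stride 4, concatenates,
refines with two 3×3×256 convolutions, classifies 1×1, and upsamples to the
input resolution. Rates and widths are the canonical DeepLabV3+ values.
Inputs not divisible by the output stride (e.g. 321, 415) are zero-padded
to the next multiple internally and the logits cropped back, so all square
sizes share one code path.

## Loss and metrics

The training objective is cross-entropy plus soft-Dice:
CE = −(1/N) Σ_n Σ_c y_{n,c} log p_{n,c} over the batch's pixels, and per
class D_c = 2Σyp / (Σy² + Σp²) computed over the whole batch with a 1e−6
smoothing term, averaged over classes; the loss is CE + (1 − mean D).
A per-pixel Dice reading is degenerate (it collapses to a counting term),
so the batch-level soft Dice is used. Evaluation uses the (K+1)×(K+1) pixel
confusion matrix: MIoU is the mean over classes of p_ii/(Σ_j p_ij + Σ_j
p_ji − p_ii) and MPA the mean of p_ii/Σ_j p_ij; classes with an empty union
(0/0) are excluded from the means. PSNR = 10·log₁₀((2ⁿ−1)²/MSE) with n = 8
bits; since the comparison pair for a segmentation result is a convention
rather than a fixed rule, we compare the RGB image masked by ground truth
against the image masked by the prediction (background zeroed), which
measures exactly the distortion the segmentation introduces. Identical
images report +inf.

## Numerical engine

No deep-learning framework is used: `semd.nn` is a compact reverse-mode
autodiff engine on float32 NumPy arrays, with convolutions lowered to
batched GEMMs (im2col in (B, C·k·k, H·W) layout) and Numba-compiled inner
loops for patch extraction/scattering, depthwise convolution, and fused
batch normalization. Pointwise (1×1) convolutions skip im2col entirely, and
a 3×3 atrous convolution whose dilation reaches beyond the feature map
(only possible at desk-scale inputs) reduces exactly to its center-tap 1×1
convolution, since the off-center taps see only zero padding — an identity,
not an approximation. Everything is single-threaded and deterministic: a
run seed fixes He-normal initialization (convolutions), unit-gain batch
norm, data shuffling, and scene generation, so identical configurations
reproduce identical loss curves bit-for-bit. Gradient correctness is tested
against central finite differences for every primitive.

Batch normalization uses eps 1e−5 and running-statistic momentum 0.1;
Adam uses (β1, β2, eps) = (0.9, 0.999, 1e−8). Softmax subtracts the row
maximum; logarithms add 1e−7 under the log.

## Synthetic scenes

The generator emulates the four strata of a standing-tree photograph
collection — single vs. multiple trees against simple vs. complex
backgrounds — because no public dataset accompanies the task. A scene is a
vertical sky gradient with a soil band; trees are tapered trunk
quadrilaterals plus canopies built from 5–8 overlapping ellipses; complex
backgrounds add a grass band and green elliptical clutter (bushes) that a
segmenter can confuse with canopy, verified by a hue test in the suite.
Masks come from the same geometry the renderer paints, so ground truth is
pixel-exact. Defaults (trunk width 5.5 % of the canvas, canopy radius 16 %,
clutter density 1) were chosen to give a plausible foreground fraction
(5–60 % of pixels) and realistic trunk/canopy proportions. What the
generator does **not** reproduce: texture-rich bark and foliage, occlusion
by other objects, lighting variation, perspective, and species morphology.
Passing tests therefore demonstrate that the architecture, losses, metrics
and pipeline are correct and that the model can learn color/shape cues —
not that it reaches photographic-benchmark accuracy.

A dataset is written as `images/`, `masks/` (VOC palette PNGs), and
`lists/train.txt` / `lists/val.txt`, split 90/10 stratified over the four
strata with a seeded shuffle. Offline augmentation doubles the training
set: each sample contributes itself plus one transformed copy (rotation
uniform in ±15°, horizontal/vertical flips with probability ½ each,
nearest-neighbor mask resampling).

## Training

The training recipe is Adam at learning rate 5e−5, batch size 8, 100
epochs, 512×512 inputs (the `TrainConfig` defaults). Two-stage fine-tuning
is supported: with externally loaded backbone weights the backbone can be
frozen for the first `freeze_backbone_epochs` epochs before joint
optimization; the package ships no pretrained weights (random He-normal
initialization is the default), so the hook exists but the desk-scale runs
train from scratch. The best-validation-MIoU checkpoint is kept.
`steps_per_epoch` / `val_steps` caps exist but default to off.

**Desk-scale study.** The acceptance suite scales the recipe down to
40 scenes at 64×64 for 50 epochs (the other hyper-parameters unchanged) so
that a full multi-seed study runs on one CPU. At this input size the
encoder's deepest maps are 8×8 at output stride 8, which the study uses:
with 4×4 maps (output stride 16) the thin trunks — about 3.5 px wide at
64² — lose too much localization. The size sweep (512/415/321) runs
inference-only on the validation split.

## Known limitations

* CPU-only and single-threaded; wall-clock is dominated by BLAS GEMMs.
* No CRF post-processing, no Xception backbone, no multi-scale test-time
  augmentation.
* The ImageNet pretraining stage of the published two-stage transfer recipe
  requires external weights; only the mechanism (freeze/unfreeze) is
  implemented.
* PSNR's reference/test pairing is a documented convention (masked-image
  comparison), not a standard.
* Checkpoints are NumPy `.npz` archives keyed by module path
  (e.g. `backbone.stem.conv.weight`); they are not portable to other
  frameworks.
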