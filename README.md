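# semd — lightweight standing-tree segmentation

`semd` segments standing trees (live, upright trees photographed in situ)
from RGB images, for forestry work that derives tree factors — crown
extent, diameter at breast height — from photographs. It implements SEMD,
a DeepLabV3+ encoder–decoder whose backbone is MobileNetV2 augmented with
squeeze-and-excitation (SE) channel attention, together with its combined
cross-entropy + Dice training objective, MIoU/MPA/PSNR evaluation, a
LabelMe/PASCAL-VOC data pipeline, and a seeded procedural generator of
standing-tree scenes with pixel-exact ground truth.

The network runs on a self-contained NumPy automatic-differentiation
engine (`semd.nn`) with Numba-compiled convolution kernels — no
deep-learning framework is required, and training is deterministic on a
single CPU.

## The model in brief

* **Backbone**: MobileNetV2 — a stride-2 stem and seven inverted-residual
  stages (1×1 expand ×t → 3×3 depthwise → 1×1 linear project, ReLU6
  activations). A depthwise-separable convolution costs
  C2/C1 = 1/N + 1/K² of a standard convolution's multiply-accumulates.
  The classification tail is removed; an SE block
  (s = σ(W₂·ReLU(W₁·z)), reduction 4) recalibrates the final 320-channel
  map, followed by an extra 3×3×512 convolution.
* **Encoder**: atrous spatial pyramid pooling over the 512-channel map —
  3×3 branches at dilations (6, 12, 18), a 1×1 branch, and a global-pool
  branch, fused to 256 channels.
* **Decoder**: the fused map is upsampled to the stride-4 low-level tap
  (24→48 channels), concatenated, refined by two 3×3×256 convolutions and
  classified per pixel.
* **Loss**: ε(Y, P) = −(1/N) Σ y log p + (1 − soft-Dice), with the Dice
  coefficient 2Σyp/(Σy²+Σp²) per class over the batch.
* **Metrics**: MIoU and MPA from the pixel confusion matrix; PSNR
  (10·log₁₀(255²/MSE)) between ground-truth-masked and prediction-masked
  images.

## Worked example

```bash
# 40 synthetic scenes (4 strata × 10) at 64×64, written as
# images/ masks/ lists/ with a 90/10 stratified split
semd synth --n 10 --canvas 64 --seed 42 --out scenes/

# train with the published recipe scaled to desk size
cat > cfg.yaml <<EOF
epochs: 50
batch_size: 8
lr: 5.0e-5
input_size: 64
output_stride: 8
seed: 1
EOF
semd train --config cfg.yaml --data scenes/ --checkpoint model.npz

# input-size robustness sweep + report
semd eval --checkpoint model.npz --data scenes/ --sizes 64
semd predict --checkpoint model.npz --out pred/ scenes/images/single_simple_0000.png
```

The training command logs one line per epoch and ends with

```
epoch  49  train_loss=0.1546  val_loss=0.1653  val_miou=0.8704
best val MIoU 0.8753 at epoch 45; checkpoint -> model.npz
```

i.e. the combined CE+Dice loss falls from ~1.3 (random initialization) to
≈0.15, and the held-out mean intersection-over-union reaches ≈0.88 — the
model has learned to separate trunks and canopies from sky, soil, and (in
complex scenes) green clutter. `semd eval` then prints a small table per
input size:

```
--- input 64×64 ---
metric               value
MIoU                0.8753
MPA                 0.9333
IoU[class 0]        0.9496
IoU[class 1]        0.8010
PSNR (dB)            19.17
```

MIoU close to 1 means predicted and true tree pixels overlap almost
perfectly; PSNR compares the image masked by the prediction against the
image masked by the truth, so higher values mean less segmentation
distortion.

## Layout

```
src/semd/nn/        autograd engine, layers, Adam, Numba kernels
src/semd/backbone.py   SE-MobileNetV2, inverted residuals, conv cost model
src/semd/deeplab.py    ASPP, decoder, the SEMD model
src/semd/losses.py     combined CE + Dice objective
src/semd/metrics.py    confusion matrix, MIoU/MPA, MSE/PSNR, reports
src/semd/data.py       VOC palette masks, LabelMe polygons, augmentation
src/semd/scenes.py     synthetic standing-tree scene generator
src/semd/train.py      training loop, evaluation harness, prediction
src/semd/cli.py        `semd synth|train|eval|predict`
```
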