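"""SE-augmented MobileNetV2 feature extractor and the separable-conv cost model.

The encoder backbone is MobileNetV2 (stem conv + seven inverted-residual
stages) with two modifications for segmentation:

* the classification tail (final 1x1 conv to 1280 channels and the average
  pool) is removed, so the deepest feature map has 320 channels;
* a squeeze-and-excitation (SE) channel-attention block recalibrates that
  320-channel map, followed by an extra 3x3 convolution to 512 channels for
  high-dimensional feature extraction.

The SE bottleneck width is a quarter of the channel count (reduction 4).
An unmodified ``MobileNetV2`` (with the 1280-channel tail) is also provided
as the classification/reference build.

``conv_cost`` gives the analytic multiply-accumulate and parameter counts of
a standard vs. depthwise-separable convolution; their ratio is the familiar
``1/N + 1/K^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor


# Inverted-residual stage settings: (expansion t, out channels c, repeats n, stride s).
# The first stage is the only one with t = 1; stride applies to the first repeat.
BOTTLENECK_SETTINGS: tuple[tuple[int, int, int, int], ...] = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)

STEM_CHANNELS = 32
LOW_LEVEL_STAGE = 1  # 24-channel stage, overall stride 4 — the decoder tap


@dataclass(frozen=True)
class InvertedResidualSpec:
    """One inverted-residual stage: expansion t, output channels c, repeats n, stride s."""

    expansion_t: int
    out_channels_c: int
    repeats_n: int
    stride_s: int

    def __post_init__(self):
        if self.expansion_t < 1 or self.out_channels_c < 1 or self.repeats_n < 1:
            raise ValueError("t, c, n must be positive")
        if self.stride_s not in (1, 2):
            raise ValueError("stride must be 1 or 2")


@dataclass(frozen=True)
class ConvCost:
    """Analytic cost of one convolution layer, standard vs. depthwise-separable.

    FLOP counts are multiply-accumulates; parameter counts assume no bias
    (batch normalization follows every convolution here).
    """

    standard_flops: int
    separable_flops: int
    standard_params: int
    separable_params: int

    @property
    def ratio(self) -> float:
        """separable_flops / standard_flops == 1/N + 1/K²."""
        return self.separable_flops / self.standard_flops


def conv_cost(k: int, m: int, n: int, f_h: int, f_w: int) -> ConvCost:
    """Cost of convolving an F_H×F_W×M map with N K×K kernels.

    Standard convolution: C1 = K²·M·N·F_H·F_W multiply-accumulates,
    P1 = K²·M·N parameters. Depthwise-separable: a K×K per-channel pass plus
    a 1×1 channel-mixing pass, C2 = K²·M·F_H·F_W + M·N·F_H·F_W and
    P2 = K²·M + M·N.
    """
    for name, v in (("k", k), ("m", m), ("n", n), ("f_h", f_h), ("f_w", f_w)):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"conv_cost: {name} must be a positive integer, got {v!r}")
    c1 = k * k * m * n * f_h * f_w
    c2 = k * k * m * f_h * f_w + m * n * f_h * f_w
    p1 = k * k * m * n
    p2 = k * k * m + m * n
    return ConvCost(c1, c2, p1, p2)


def relu6(x):
    """Clipped rectifier min(max(0, x), 6); accepts arrays or Tensors."""
    if isinstance(x, Tensor):
        return nn.relu6(x)
    return np.minimum(np.maximum(np.asarray(x, dtype=np.float32), 0), 6)


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool each channel to a scalar z_c.  Excite:
    s = sigmoid(W2 · ReLU(W1 · z)) with a bottleneck of width C/reduction.
    Reweight: scale channel c of the input by s_c ∈ (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        rng = rng or np.random.default_rng()
        hidden = channels // reduction
        self.w1 = Tensor(nn.he_normal(rng, (hidden, channels), channels), requires_grad=True)
        self.w2 = Tensor(nn.he_normal(rng, (channels, hidden), hidden), requires_grad=True)
        self.channels, self.reduction = channels, reduction

    def scale(self, x: Tensor) -> Tensor:
        """The excitation factors s, shape (B, C)."""
        if x.shape[1] != self.channels:
            raise ValueError(f"SEBlock: expected {self.channels} channels, got {x.shape[1]}")
        z = x.mean(axis=(2, 3))                       # squeeze: (B, C)
        h = nn.relu(nn.matmul(z, nn.transpose(self.w1, (1, 0))))
        return nn.sigmoid(nn.matmul(h, nn.transpose(self.w2, (1, 0))))

    def forward(self, x: Tensor) -> Tensor:
        s = self.scale(x)
        b, c = s.shape
        return x * s.reshape((b, c, 1, 1))


class ConvBNReLU6(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 dilation: int = 1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        pad = (kernel - 1) // 2 * dilation
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride=stride, padding=pad,
                              dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu6(self.bn(self.conv(x)))


class InvertedResidual(nn.Module):
    """MobileNetV2 block: 1×1 expand (×t) → ReLU6 → 3×3 depthwise → ReLU6 →
    1×1 linear projection, with an identity skip iff stride 1 and matching
    channel counts.  A per-block SE variant is available for experimentation.
    """

    def __init__(self, in_ch: int, out_ch: int, *, expansion: int, stride: int,
                 dilation: int = 1, se: bool = False, se_reduction: int = 4,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        hidden = in_ch * expansion
        self.use_skip = stride == 1 and in_ch == out_ch
        self.expand = None if expansion == 1 else ConvBNReLU6(in_ch, hidden, 1, rng=rng)
        self.dw = nn.DepthwiseConv2d(hidden, 3, stride=stride, padding=dilation,
                                     dilation=dilation, rng=rng)
        self.dw_bn = nn.BatchNorm2d(hidden)
        self.project = nn.Conv2d(hidden, out_ch, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(out_ch)
        self.se = SEBlock(hidden, se_reduction, rng=rng) if se else None

    def forward(self, x: Tensor) -> Tensor:
        h = x if self.expand is None else self.expand(x)
        h = nn.relu6(self.dw_bn(self.dw(h)))
        if self.se is not None:
            h = self.se(h)
        h = self.project_bn(self.project(h))
        return x + h if self.use_skip else h


def _build_stages(specs, *, output_stride: int, per_block_se: bool,
                  se_reduction: int, rng) -> list[nn.Sequential]:
    """Instantiate the inverted-residual stages, converting stride to dilation
    once the requested output stride is reached (the DeepLab trick)."""
    stages = []
    in_ch = STEM_CHANNELS
    current_stride = 2  # stem already divides by 2
    dilation = 1
    for spec in specs:
        spec = InvertedResidualSpec(*spec) if not isinstance(spec, InvertedResidualSpec) else spec
        blocks = []
        for rep in range(spec.repeats_n):
            stride = spec.stride_s if rep == 0 else 1
            if stride == 2 and current_stride >= output_stride:
                stride, block_dil = 1, dilation
                if rep == 0:
                    dilation *= 2
                    block_dil = dilation
            else:
                block_dil = dilation
                if stride == 2:
                    current_stride *= 2
            blocks.append(InvertedResidual(
                in_ch, spec.out_channels_c, expansion=spec.expansion_t,
                stride=stride, dilation=block_dil, se=per_block_se,
                se_reduction=se_reduction, rng=rng))
            in_ch = spec.out_channels_c
        stages.append(nn.Sequential(*blocks))
    return stages


class SEMobileNetV2(nn.Module):
    """The segmentation backbone: MobileNetV2 stages (tail removed), one SE
    block on the final 320-channel map, then a 3×3 convolution to
    ``extra_conv_width`` (512) channels.

    ``forward`` returns ``(low, high)``: the 24-channel stride-4 tap for the
    decoder and the deepest feature map.
    """

    def __init__(self, *, output_stride: int = 16, se_enabled: bool = True,
                 se_reduction: int = 4, extra_conv_width: int = 512,
                 per_block_se: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if output_stride not in (8, 16, 32):
            raise ValueError("output_stride must be 8, 16 or 32")
        rng = rng or np.random.default_rng()
        self.stem = ConvBNReLU6(3, STEM_CHANNELS, 3, stride=2, rng=rng)
        self.stages = _build_stages(BOTTLENECK_SETTINGS, output_stride=output_stride,
                                    per_block_se=per_block_se,
                                    se_reduction=se_reduction, rng=rng)
        final_ch = BOTTLENECK_SETTINGS[-1][1]
        self.se = SEBlock(final_ch, se_reduction, rng=rng) if se_enabled else None
        self.extra = ConvBNReLU6(final_ch, extra_conv_width, 3, rng=rng)
        self.output_stride = output_stride
        self.low_level_channels = BOTTLENECK_SETTINGS[LOW_LEVEL_STAGE][1]
        self.out_channels = extra_conv_width

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.stem(x)
        low = None
        for i, stage in enumerate(self.stages):
            h = stage(h)
            if i == LOW_LEVEL_STAGE:
                low = h
        if self.se is not None:
            h = self.se(h)
        return low, self.extra(h)

    def stage_trace(self, input_hw: int = 224) -> list[tuple[int, int]]:
        """(spatial size, channels) after the stem and after each stage,
        measured by a dummy forward pass."""
        self.eval()
        trace = []
        with nn.no_grad():
            h = self.stem(Tensor(np.zeros((1, 3, input_hw, input_hw), np.float32)))
            trace.append((h.shape[2], h.shape[1]))
            for stage in self.stages:
                h = stage(h)
                trace.append((h.shape[2], h.shape[1]))
        return trace


class ClassifierHead(nn.Module):
    """Pretraining head: global average pooling, then a hidden fully connected
    layer with ReLU, then the class logits."""

    def __init__(self, in_ch: int, num_classes: int, hidden: int = 256,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.fc1 = nn.Linear(in_ch, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, num_classes, rng=rng)

    def forward(self, features: Tensor) -> Tensor:
        z = features.mean(axis=(2, 3))
        return self.fc2(nn.relu(self.fc1(z)))


class MobileNetV2(nn.Module):
    """The unmodified classification network (reference build): stem, seven
    inverted-residual stages, 1×1 convolution to 1280 channels, global pool,
    1×1 classifier."""

    def __init__(self, num_classes: int = 1000,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stem = ConvBNReLU6(3, STEM_CHANNELS, 3, stride=2, rng=rng)
        self.stages = _build_stages(BOTTLENECK_SETTINGS, output_stride=32,
                                    per_block_se=False, se_reduction=4, rng=rng)
        self.head_conv = ConvBNReLU6(BOTTLENECK_SETTINGS[-1][1], 1280, 1, rng=rng)
        self.classifier = nn.Conv2d(1280, num_classes, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        for stage in self.stages:
            h = stage(h)
        h = self.head_conv(h)
        pooled = h.mean(axis=(2, 3), keepdims=True)
        logits = self.classifier(pooled)
        b, k = logits.shape[0], logits.shape[1]
        return logits.reshape((b, k))

    def stage_trace(self, input_hw: int = 224) -> list[tuple[int, int]]:
        """(spatial size, channels) trace including the 1280-channel tail."""
        self.eval()
        trace = []
        with nn.no_grad():
            h = self.stem(Tensor(np.zeros((1, 3, input_hw, input_hw), np.float32)))
            trace.append((h.shape[2], h.shape[1]))
            for stage in self.stages:
                h = stage(h)
                trace.append((h.shape[2], h.shape[1]))
            h = self.head_conv(h)
            trace.append((h.shape[2], h.shape[1]))
            pooled = h.mean(axis=(2, 3), keepdims=True)
            trace.append((pooled.shape[2], pooled.shape[1]))
        return trace


def build_backbone(*, se_enabled: bool = True, extra_conv_width: int = 512,
                   se_reduction: int = 4, output_stride: int = 16,
                   per_block_se: bool = False,
                   rng: Optional[np.random.Generator] = None) -> SEMobileNetV2:
    """Construct the segmentation backbone with the documented defaults."""
    return SEMobileNetV2(output_stride=output_stride, se_enabled=se_enabled,
                         se_reduction=se_reduction, extra_conv_width=extra_conv_width,
                         per_block_se=per_block_se, rng=rng)
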