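"""SEMD: DeepLabV3+ encoder-decoder around the SE-MobileNetV2 backbone.

Encoder: the backbone's deepest feature map is fed through atrous spatial
pyramid pooling (ASPP) — parallel 3×3 convolutions whose kernel taps are
spaced by increasing dilation rates, a 1×1 branch, and a global-average-pool
branch — and fused to 256 channels.  Decoder: the fused map is upsampled to
the backbone's stride-4 tap, concatenated with a 1×1-projected low-level
map, refined by two 3×3 convolutions and classified per pixel; a final
bilinear upsample restores the input resolution.

Input sizes need not be divisible by the output stride: inputs are
zero-padded to the next multiple internally and the logits cropped back, so
the 512/415/321 square sizes all run through one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import SEMobileNetV2, build_backbone


@dataclass(frozen=True)
class ASPPConfig:
    """Atrous spatial pyramid pooling branches.

    ``atrous_rates`` are the dilations of the 3×3 branches (strictly
    increasing); a 1×1 branch and, optionally, a global-pool branch are
    always added, so the branch count is ``len(atrous_rates) + 2``.
    """

    atrous_rates: tuple[int, ...] = (6, 12, 18)
    branch_channels: int = 256
    global_pool_branch: bool = True

    def __post_init__(self):
        if any(r < 1 for r in self.atrous_rates):
            raise ValueError("atrous rates must be >= 1")
        if list(self.atrous_rates) != sorted(set(self.atrous_rates)):
            raise ValueError("atrous rates must be strictly increasing")


@dataclass(frozen=True)
class SEMDConfig:
    """Model-level configuration.

    num_classes counts the background, so tree-vs-background is 2.
    output_stride is the encoder's input/feature resolution ratio; at
    output stride 8 the ASPP rates are doubled.
    """

    num_classes: int = 2
    output_stride: int = 16
    input_size: int = 512
    se_enabled: bool = True
    se_reduction: int = 4
    extra_conv_width: int = 512
    aspp: ASPPConfig = field(default_factory=ASPPConfig)
    decoder_channels: int = 256
    low_level_channels: int = 48

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least background + one foreground class")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")


class ConvBNReLU(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, dilation: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        pad = (kernel - 1) // 2 * dilation
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, padding=pad, dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.conv(x)))


def atrous_conv(x: Tensor, weight: Tensor, rate: int) -> Tensor:
    """3×3 convolution with kernel taps spaced by `rate`; output size preserved."""
    if rate < 1:
        raise ValueError("dilation rate must be >= 1")
    return nn.conv2d(x, weight, stride=1, padding=rate, dilation=rate)


class ASPP(nn.Module):
    """Multi-scale context: 1×1 branch, one 3×3 atrous branch per rate, and a
    global-average-pool branch upsampled back, concatenated and fused 1×1."""

    def __init__(self, in_ch: int, cfg: ASPPConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        ch = cfg.branch_channels
        self.branch1x1 = ConvBNReLU(in_ch, ch, 1, rng=rng)
        self.atrous = [ConvBNReLU(in_ch, ch, 3, dilation=r, rng=rng)
                       for r in cfg.atrous_rates]
        self.pool_branch = ConvBNReLU(in_ch, ch, 1, rng=rng) if cfg.global_pool_branch else None
        n_branches = 1 + len(self.atrous) + (1 if self.pool_branch else 0)
        self.fuse = ConvBNReLU(n_branches * ch, ch, 1, rng=rng)
        self.cfg = cfg

    @property
    def n_branches(self) -> int:
        return 1 + len(self.atrous) + (1 if self.pool_branch else 0)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        outs = [self.branch1x1(x)]
        outs += [branch(x) for branch in self.atrous]
        if self.pool_branch is not None:
            pooled = x.mean(axis=(2, 3), keepdims=True)
            outs.append(nn.upsample_bilinear(self.pool_branch(pooled), (h, w)))
        return self.fuse(nn.concat(outs, axis=1))


class Decoder(nn.Module):
    """Refine: project the low-level tap to a small width, concatenate with the
    upsampled ASPP output, apply two 3×3 convolutions, classify 1×1."""

    def __init__(self, low_ch: int, fused_ch: int, cfg: SEMDConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.project = ConvBNReLU(low_ch, cfg.low_level_channels, 1, rng=rng)
        dch = cfg.decoder_channels
        self.refine1 = ConvBNReLU(cfg.low_level_channels + fused_ch, dch, 3, rng=rng)
        self.refine2 = ConvBNReLU(dch, dch, 3, rng=rng)
        self.classifier = nn.Conv2d(dch, cfg.num_classes, 1, bias=True, rng=rng)

    def forward(self, low: Tensor, fused: Tensor) -> Tensor:
        low = self.project(low)
        fused = nn.upsample_bilinear(fused, (low.shape[2], low.shape[3]))
        h = nn.concat([low, fused], axis=1)
        h = self.refine2(self.refine1(h))
        return self.classifier(h)


class SEMD(nn.Module):
    """The full segmentation network.

    ``forward`` returns per-pixel logits B×num_classes×H×W at the input
    resolution; ``predict_proba`` applies the softmax and ``predict`` the
    per-pixel argmax.
    """

    def __init__(self, cfg: SEMDConfig = SEMDConfig(), *,
                 rng: Optional[np.random.Generator] = None,
                 backbone: Optional[SEMobileNetV2] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        aspp_cfg = cfg.aspp
        if cfg.output_stride == 8:
            aspp_cfg = ASPPConfig(tuple(2 * r for r in aspp_cfg.atrous_rates),
                                  aspp_cfg.branch_channels, aspp_cfg.global_pool_branch)
        self.backbone = backbone if backbone is not None else build_backbone(
            se_enabled=cfg.se_enabled, extra_conv_width=cfg.extra_conv_width,
            se_reduction=cfg.se_reduction, output_stride=cfg.output_stride, rng=rng)
        self.aspp = ASPP(self.backbone.out_channels, aspp_cfg, rng=rng)
        self.decoder = Decoder(self.backbone.low_level_channels,
                               aspp_cfg.branch_channels, cfg, rng=rng)
        self.cfg = cfg

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected B×3×H×W input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        os = self.cfg.output_stride
        pad_h = (-h) % os
        pad_w = (-w) % os
        x = nn.pad2d(x, pad_h, pad_w)
        low, high = self.backbone(x)
        fused = self.aspp(high)
        logits = self.decoder(low, fused)
        logits = nn.upsample_bilinear(logits, (h + pad_h, w + pad_w))
        if pad_h or pad_w:
            logits = nn.crop2d(logits, h, w)
        return logits

    def predict_proba(self, x) -> Tensor:
        """Softmax class probabilities at every pixel (sum to 1 per pixel)."""
        return nn.softmax(self.forward(x), axis=1)

    def predict(self, x) -> np.ndarray:
        """Integer class map B×H×W (argmax over classes), computed without
        recording gradients."""
        with nn.no_grad():
            logits = self.forward(x)
        return np.argmax(logits.data, axis=1).astype(np.uint8)
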