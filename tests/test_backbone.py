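"""Backbone: clipped rectifier, separable-convolution cost model,
squeeze-and-excitation block vs. a scalar oracle, inverted residuals, and
the stage-by-stage shape contract of the network structure tables."""

import numpy as np
import pytest

from semd import (BOTTLENECK_SETTINGS, InvertedResidual, InvertedResidualSpec,
                  MobileNetV2, SEBlock, SEMobileNetV2, build_backbone,
                  conv_cost, relu6, nn)

# (spatial, channels) after the stem and each inverted-residual stage for a
# 224×224×3 input, as published for MobileNetV2
EXPECTED_TRACE = [(112, 32), (112, 16), (56, 24), (28, 32), (14, 64),
                  (14, 96), (7, 160), (7, 320)]


# ---- ReLU6 -------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(10.0, 6.0), (-3.0, 0.0), (3.5, 3.5), (6.0, 6.0)])
def test_relu6_clamps_above_six_and_below_zero(x, expected):
    assert relu6(np.array([x])) == pytest.approx(expected)


def test_relu6_range_for_arbitrary_input(rng):
    out = relu6(rng.standard_normal(1000) * 100)
    assert out.min() >= 0.0 and out.max() <= 6.0


# ---- cost model --------------------------------------------------------------

def test_conv_cost_reference_case():
    cost = conv_cost(3, 32, 32, 112, 112)
    assert cost.ratio == pytest.approx(1 / 32 + 1 / 9, abs=1e-12)
    # evaluate both closed forms independently
    assert cost.standard_flops == 3 * 3 * 32 * 32 * 112 * 112
    assert cost.separable_flops == 3 * 3 * 32 * 112 * 112 + 32 * 32 * 112 * 112


def test_conv_cost_degenerate_1x1_single_kernel():
    assert conv_cost(1, 8, 1, 4, 4).ratio == pytest.approx(2.0)


@pytest.mark.parametrize("k", [1, 3, 5, 7])
def test_conv_cost_ratio_closed_form_sweep(k):
    for n in range(1, 65):
        cost = conv_cost(k, 16, n, 8, 8)
        assert cost.ratio == pytest.approx(1 / n + 1 / k ** 2, rel=1e-12)


@pytest.mark.parametrize("bad", [0, -1, 2.5])
def test_conv_cost_rejects_non_positive_arguments(bad):
    with pytest.raises(ValueError):
        conv_cost(3, bad, 4, 8, 8)


def test_instantiated_separable_layer_matches_cost_formulas(rng):
    """Parameter and multiply-accumulate counts of a real depthwise-separable
    layer (depthwise k×k + pointwise 1×1, no bias) equal the calculator."""
    k, m, n, f = 3, 6, 10, 12
    dw = nn.DepthwiseConv2d(m, k, padding=k // 2, rng=rng)
    pw = nn.Conv2d(m, n, 1, rng=rng)
    cost = conv_cost(k, m, n, f, f)
    assert dw.weight.data.size + pw.weight.data.size == cost.separable_params

    x = nn.Tensor(rng.standard_normal((1, m, f, f)).astype(np.float32))
    mid = nn.depthwise_conv2d(x, dw.weight, padding=k // 2)
    out = nn.conv2d(mid, pw.weight)
    # enumerate multiply-accumulates from the instantiated shapes:
    # each depthwise output pixel uses k² products, each pointwise uses m
    macs = mid.data[0].size * k * k + out.data[0].size * m
    assert macs == cost.separable_flops

    dense = nn.Conv2d(m, n, k, padding=k // 2, rng=rng)
    assert dense.weight.data.size == cost.standard_params
    dense_out = dense(x)
    assert dense_out.data[0].size * k * k * m == cost.standard_flops


# ---- squeeze-and-excitation --------------------------------------------------

def se_oracle(u, w1, w2):
    """Scalar-loop reference: squeeze to per-channel means, two-layer
    excitation with ReLU then sigmoid, rescale each channel."""
    b, c, h, w = u.shape
    out = np.zeros_like(u)
    scales = np.zeros((b, c))
    for bi in range(b):
        z = np.zeros(c)
        for ci in range(c):
            acc = 0.0
            for i in range(h):
                for j in range(w):
                    acc += u[bi, ci, i, j]
            z[ci] = acc / (h * w)
        hidden = np.maximum(w1 @ z, 0.0)
        s = 1.0 / (1.0 + np.exp(-(w2 @ hidden)))
        for ci in range(c):
            scales[bi, ci] = s[ci]
            for i in range(h):
                for j in range(w):
                    out[bi, ci, i, j] = s[ci] * u[bi, ci, i, j]
    return out, scales


def test_se_block_matches_scalar_oracle(rng):
    se = SEBlock(4, reduction=4, rng=rng)
    u = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
    out = se(nn.Tensor(u))
    ref, scales = se_oracle(u.astype(np.float64), se.w1.data.astype(np.float64),
                            se.w2.data.astype(np.float64))
    np.testing.assert_allclose(out.data, ref, atol=1e-6)
    assert np.all(scales > 0) and np.all(scales < 1)


def test_se_block_constant_channel_squeezes_to_value(rng):
    se = SEBlock(8, reduction=4, rng=rng)
    u = np.zeros((1, 8, 5, 5), np.float32)
    for c in range(8):
        u[0, c] = c - 3.5
    z = nn.Tensor(u).mean(axis=(2, 3))
    np.testing.assert_allclose(z.data[0], np.arange(8) - 3.5, atol=1e-6)


def test_se_block_zero_weights_halve_input(rng):
    se = SEBlock(4, reduction=2, rng=rng)
    se.w1.data[:] = 0
    se.w2.data[:] = 0
    u = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
    out = se(nn.Tensor(u))
    np.testing.assert_allclose(out.data, u / 2, atol=1e-6)


def test_se_block_scale_forced_to_one_is_identity(rng):
    """Removing the attention (unit scale) leaves the input unchanged."""
    se = SEBlock(4, reduction=2, rng=rng)
    u = rng.standard_normal((1, 4, 3, 3)).astype(np.float32)
    s = se.scale(nn.Tensor(u))
    out = nn.Tensor(u) * (s * 0.0 + 1.0).reshape((1, 4, 1, 1))
    np.testing.assert_allclose(out.data, u, atol=1e-6)


def test_se_block_rejects_channel_mismatch(rng):
    se = SEBlock(8, rng=rng)
    with pytest.raises(ValueError):
        se(nn.Tensor(np.zeros((1, 4, 3, 3), np.float32)))


# ---- inverted residuals ------------------------------------------------------

def test_inverted_residual_spec_validation():
    with pytest.raises(ValueError):
        InvertedResidualSpec(6, 24, 2, 3)
    with pytest.raises(ValueError):
        InvertedResidualSpec(0, 24, 2, 1)


def test_inverted_residual_table_row_shapes(rng):
    """The (t=6, c=24, n=2, s=2) stage maps 112²×16 to 56²×24 twice."""
    b1 = InvertedResidual(16, 24, expansion=6, stride=2, rng=rng)
    b2 = InvertedResidual(24, 24, expansion=6, stride=1, rng=rng)
    x = nn.Tensor(np.zeros((1, 16, 112, 112), np.float32))
    with nn.no_grad():
        h1 = b1(x)
        h2 = b2(h1)
    assert h1.shape == (1, 24, 56, 56)
    assert h2.shape == (1, 24, 56, 56)
    assert b1.expand.conv.weight.shape[0] == 96  # 16 × t


def test_inverted_residual_zero_weights_is_identity_with_skip(rng):
    block = InvertedResidual(8, 8, expansion=6, stride=1, rng=rng)
    block.eval()
    for _, p in block.named_parameters():
        if p.data.ndim == 4:
            p.data[:] = 0
    # zero convs => residual branch contributes beta (0) only
    for mod in block.modules():
        if isinstance(mod, nn.BatchNorm2d):
            mod.gamma.data[:] = 1
            mod.beta.data[:] = 0
    x = np.random.default_rng(0).standard_normal((1, 8, 6, 6)).astype(np.float32)
    with nn.no_grad():
        out = block(nn.Tensor(x))
    np.testing.assert_allclose(out.data, x, atol=1e-6)


# ---- full backbone -----------------------------------------------------------

def test_backbone_stage_trace_matches_structure_table(rng):
    bb = build_backbone(output_stride=32, rng=rng)
    assert bb.stage_trace(224) == EXPECTED_TRACE


def test_reference_classifier_build_has_1280_channel_tail(rng):
    ref = MobileNetV2(num_classes=10, rng=rng)
    trace = ref.stage_trace(224)
    assert trace[:8] == EXPECTED_TRACE
    assert trace[8] == (7, 1280)
    assert trace[9] == (1, 1280)


def test_backbone_taps_at_output_stride_16(rng):
    bb = build_backbone(output_stride=16, rng=rng)
    with nn.no_grad():
        low, high = bb(nn.Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    assert low.shape == (1, 24, 16, 16)      # stride-4 decoder tap
    assert high.shape == (1, 512, 4, 4)      # SE + extra 3×3×512 conv

    bb_no_se = build_backbone(output_stride=16, se_enabled=False, rng=rng)
    assert bb_no_se.se is None


def test_backbone_parameter_count_matches_analytic_sum(rng):
    """Total conv parameters equal the cost-model formulas summed layer-wise."""
    bb = build_backbone(output_stride=32, se_enabled=False,
                        extra_conv_width=512, rng=rng)
    analytic = 3 * 3 * 3 * 32  # stem
    in_ch = 32
    for t, c, n, s in BOTTLENECK_SETTINGS:
        for rep in range(n):
            hidden = in_ch * t
            if t != 1:
                analytic += in_ch * hidden        # expand 1×1
            analytic += 3 * 3 * hidden            # depthwise
            analytic += hidden * c                # project 1×1
            in_ch = c
    analytic += 3 * 3 * 320 * 512                 # extra conv
    measured = sum(p.data.size for name, p in bb.named_parameters()
                   if "weight" in name and p.data.ndim == 4)
    assert measured == analytic
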