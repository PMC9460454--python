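"""Engine-level checks: analytic gradients vs. central differences,
inference-mode behaviour, and optimizer sanity."""

import numpy as np
import pytest

from semd import nn


def _numeric_grad(build, param, idx, eps=1e-2):
    orig = param.data[idx]
    param.data[idx] = orig + eps
    lp = build().item()
    param.data[idx] = orig - eps
    lm = build().item()
    param.data[idx] = orig
    return (lp - lm) / (2 * eps)


def _check(build, params, rng, n_probes=4, rtol=2e-2):
    loss = build()
    for p in params:
        p.grad = None
    loss.backward()
    for p in params:
        flat_idx = rng.choice(p.data.size, min(n_probes, p.data.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.data.shape)
            num = _numeric_grad(build, p, idx)
            ana = p.grad[idx]
            assert ana == pytest.approx(num, rel=rtol, abs=2e-3), (build, idx)


@pytest.fixture()
def xw(rng):
    x = nn.Tensor(rng.standard_normal((2, 3, 9, 9)).astype(np.float32),
                  requires_grad=True)
    w = nn.Tensor(rng.standard_normal((4, 3, 3, 3)).astype(np.float32) * 0.3,
                  requires_grad=True)
    return x, w


@pytest.mark.parametrize("stride,padding,dilation", [
    (1, 1, 1), (2, 1, 1), (1, 2, 2), (1, 9, 9),  # last: center-tap shortcut
])
def test_conv2d_gradients_match_finite_differences(xw, rng, stride, padding, dilation):
    x, w = xw
    _check(lambda: (nn.conv2d(x, w, stride=stride, padding=padding,
                              dilation=dilation) ** 2).mean(), [x, w], rng)


@pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
def test_depthwise_gradients_match_finite_differences(rng, stride, dilation):
    x = nn.Tensor(rng.standard_normal((2, 3, 9, 9)).astype(np.float32),
                  requires_grad=True)
    w = nn.Tensor(rng.standard_normal((3, 1, 3, 3)).astype(np.float32) * 0.3,
                  requires_grad=True)
    _check(lambda: (nn.depthwise_conv2d(x, w, stride=stride, padding=dilation,
                                        dilation=dilation) ** 2).mean(), [x, w], rng)


def test_pointwise_conv_matches_einsum_reference(rng):
    x = rng.standard_normal((2, 5, 6, 6)).astype(np.float32)
    w = rng.standard_normal((7, 5, 1, 1)).astype(np.float32)
    out = nn.conv2d(nn.Tensor(x), nn.Tensor(w))
    ref = np.einsum("bchw,oc->bohw", x, w[:, :, 0, 0])
    np.testing.assert_allclose(out.data, ref, atol=1e-5)


def test_batch_norm_gradients_and_statistics(rng):
    x = nn.Tensor(rng.standard_normal((3, 4, 5, 5)).astype(np.float32) * 2 + 1,
                  requires_grad=True)
    gamma = nn.Tensor(np.full(4, 1.3, np.float32), requires_grad=True)
    beta = nn.Tensor(np.arange(4, dtype=np.float32) * 0.1, requires_grad=True)

    out, mean, var = nn.tensor.batch_norm(x, gamma, beta, 1e-5)
    np.testing.assert_allclose(mean, x.data.mean(axis=(0, 2, 3)), atol=1e-5)
    # normalized output has ~zero mean, gamma/beta affine applied
    np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), beta.data, atol=1e-4)
    _check(lambda: (nn.tensor.batch_norm(x, gamma, beta, 1e-5)[0] ** 3).mean(),
           [x, gamma, beta], rng)


def test_upsample_bilinear_and_softmax_gradients(rng):
    x = nn.Tensor(rng.standard_normal((2, 3, 6, 6)).astype(np.float32),
                  requires_grad=True)
    _check(lambda: (nn.upsample_bilinear(x, (13, 13)) ** 2).mean(), [x], rng)
    _check(lambda: -(nn.log(nn.softmax(x, axis=1), eps=1e-7)).mean(), [x], rng)


def test_upsample_bilinear_preserves_constants():
    x = nn.Tensor(np.full((1, 2, 5, 5), 3.25, np.float32))
    out = nn.upsample_bilinear(x, (12, 12))
    np.testing.assert_allclose(out.data, 3.25, atol=1e-6)


def test_no_grad_builds_no_graph():
    x = nn.Tensor(np.ones((1, 1, 4, 4), np.float32), requires_grad=True)
    w = nn.Tensor(np.ones((1, 1, 3, 3), np.float32), requires_grad=True)
    with nn.no_grad():
        out = nn.conv2d(x, w, padding=1)
    assert out._parents == () and out._backward is None


def test_adam_converges_on_quadratic():
    p = nn.Tensor(np.array([5.0, -3.0], np.float32), requires_grad=True)
    opt = nn.Adam([p], lr=0.2)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2


def test_backward_accumulates_over_reused_tensors(rng):
    x = nn.Tensor(np.array([2.0], np.float32), requires_grad=True)
    y = x * x + x * 3.0   # dy/dx = 2x + 3 = 7
    y.backward()
    assert x.grad[0] == pytest.approx(7.0)
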