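"""Numba-compiled inner loops for the convolution primitives.

These kernels keep the hot paths single-pass and allocation-free; all array
layouts are NCHW with patch matrices in (B, C·k·k, Ho·Wo) batched-GEMM form.
Loops are ordered so the innermost axis is contiguous and SIMD-friendly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_F = "float32"


@njit(f"void({_F}[:,:,:,::1], int64, int64, int64, int64, {_F}[:,:,::1])",
      cache=True, fastmath=True)
def im2col(xp, k, stride, dilation, ho, col):
    """Fill col (B, C*k*k, Ho*Wo) with k×k patches of the padded input."""
    b_n, c_n = xp.shape[0], xp.shape[1]
    wo = col.shape[2] // ho
    for b in range(b_n):
        for c in range(c_n):
            for i in range(k):
                for j in range(k):
                    row = (c * k + i) * k + j
                    oi = i * dilation
                    oj = j * dilation
                    for y in range(ho):
                        src = xp[b, c, oi + y * stride]
                        dst = col[b, row]
                        base = y * wo
                        for x in range(wo):
                            dst[base + x] = src[oj + x * stride]


@njit(f"void({_F}[:,:,::1], int64, int64, int64, int64, {_F}[:,:,:,::1])",
      cache=True, fastmath=True)
def col2im(gcol, k, stride, dilation, ho, gxp):
    """Scatter-add patch gradients (B, C*k*k, Ho*Wo) back onto the padded input."""
    b_n, c_n = gxp.shape[0], gxp.shape[1]
    wo = gcol.shape[2] // ho
    for b in range(b_n):
        for c in range(c_n):
            for i in range(k):
                for j in range(k):
                    row = (c * k + i) * k + j
                    oi = i * dilation
                    oj = j * dilation
                    for y in range(ho):
                        src = gcol[b, row]
                        dst = gxp[b, c, oi + y * stride]
                        base = y * wo
                        for x in range(wo):
                            dst[oj + x * stride] += src[base + x]


@njit(f"void({_F}[::1], {_F}[::1], {_F}[::1], {_F}[::1], float64, float64, "
      "float64, float64, float64)", cache=True, fastmath=True)
def adam_step(p, g, m, v, lr, beta1, beta2, eps, t):
    """One fused Adam update over a flattened parameter array."""
    b1t = 1.0 - beta1 ** t
    b2t = 1.0 - beta2 ** t
    for i in range(p.size):
        gi = g[i]
        mi = beta1 * m[i] + (1.0 - beta1) * gi
        vi = beta2 * v[i] + (1.0 - beta2) * gi * gi
        m[i] = mi
        v[i] = vi
        p[i] -= lr * (mi / b1t) / (np.sqrt(vi / b2t) + eps)


@njit(f"void({_F}[:,:,:,::1], {_F}[::1], {_F}[::1])", cache=True, fastmath=True)
def channel_stats(x, mean, var):
    """Per-channel mean and biased variance of a B×C×H×W tensor, one pass."""
    b_n, c_n, h_n, w_n = x.shape
    n = np.float64(b_n * h_n * w_n)
    for c in range(c_n):
        s = 0.0
        s2 = 0.0
        for b in range(b_n):
            for y in range(h_n):
                xr = x[b, c, y]
                for xi in range(w_n):
                    v = np.float64(xr[xi])
                    s += v
                    s2 += v * v
        mu = s / n
        mean[c] = mu
        var[c] = max(s2 / n - mu * mu, 0.0)


@njit(f"void({_F}[:,:,:,::1], {_F}[:,:,:,::1])", cache=True, fastmath=True)
def relu6_fwd(x, out):
    xf = x.reshape(x.size)
    of = out.reshape(out.size)
    for i in range(xf.size):
        v = xf[i]
        of[i] = 0.0 if v < 0.0 else (6.0 if v > 6.0 else v)


@njit(f"void({_F}[:,:,:,::1], {_F}[:,:,:,::1], {_F}[:,:,:,::1])",
      cache=True, fastmath=True)
def relu6_bwd(x, g, gx):
    xf = x.reshape(x.size)
    gf = g.reshape(g.size)
    of = gx.reshape(gx.size)
    for i in range(xf.size):
        v = xf[i]
        of[i] = gf[i] if (v > 0.0) and (v < 6.0) else 0.0


@njit(f"void({_F}[:,:,:,::1], {_F}[::1], {_F}[::1], {_F}[::1], {_F}[::1], "
      f"{_F}[:,:,:,::1], {_F}[:,:,:,::1])", cache=True, fastmath=True)
def bn_fwd(x, gamma, beta, mean, inv_sigma, xhat, out):
    """Normalize + affine in one pass, storing xhat for the backward pass."""
    b_n, c_n, h_n, w_n = x.shape
    for b in range(b_n):
        for c in range(c_n):
            mu = mean[c]
            s = inv_sigma[c]
            ga = gamma[c]
            be = beta[c]
            for y in range(h_n):
                xr = x[b, c, y]
                xh = xhat[b, c, y]
                orow = out[b, c, y]
                for xi in range(w_n):
                    v = (xr[xi] - mu) * s
                    xh[xi] = v
                    orow[xi] = v * ga + be


@njit(f"void({_F}[:,:,:,::1], {_F}[:,:,:,::1], {_F}[::1], {_F}[::1], "
      f"{_F}[::1], {_F}[::1], {_F}[:,:,:,::1])", cache=True, fastmath=True)
def bn_bwd(g, xhat, gamma, inv_sigma, dgamma, dbeta, gx):
    """Input gradient of batch normalization (training mode).

    dgamma/dbeta must be zero-filled on entry; gx may alias nothing.
    """
    b_n, c_n, h_n, w_n = g.shape
    n = np.float32(b_n * h_n * w_n)
    for c in range(c_n):
        sg = np.float32(0.0)
        sgx = np.float32(0.0)
        for b in range(b_n):
            for y in range(h_n):
                gr = g[b, c, y]
                xh = xhat[b, c, y]
                for xi in range(w_n):
                    sg += gr[xi]
                    sgx += gr[xi] * xh[xi]
        dgamma[c] += sgx
        dbeta[c] += sg
        scale = gamma[c] * inv_sigma[c]
        mg = sg / n
        mgx = sgx / n
        for b in range(b_n):
            for y in range(h_n):
                gr = g[b, c, y]
                xh = xhat[b, c, y]
                orow = gx[b, c, y]
                for xi in range(w_n):
                    orow[xi] = scale * (gr[xi] - mg - xh[xi] * mgx)


@njit(f"void({_F}[:,:,:,::1], {_F}[:,:,::1], int64, int64, {_F}[:,:,:,::1])",
      cache=True, fastmath=True)
def depthwise_fwd(xp, w, stride, dilation, out):
    """out[b,c] = xp[b,c] ⊛ w[c] (per-channel k×k convolution)."""
    b_n, c_n, ho, wo = out.shape
    k = w.shape[1]
    for b in range(b_n):
        for c in range(c_n):
            for y in range(ho):
                dst = out[b, c, y]
                for x in range(wo):
                    dst[x] = 0.0
                yb = y * stride
                for i in range(k):
                    src = xp[b, c, yb + i * dilation]
                    for j in range(k):
                        wv = w[c, i, j]
                        oj = j * dilation
                        for x in range(wo):
                            dst[x] += src[oj + x * stride] * wv


@njit(f"void({_F}[:,:,:,::1], {_F}[:,:,::1], {_F}[:,:,:,::1], int64, int64, "
      f"{_F}[:,:,:,::1], {_F}[:,:,::1])", cache=True, fastmath=True)
def depthwise_bwd(xp, w, g, stride, dilation, gxp, gw):
    """Accumulate input and weight gradients of depthwise_fwd in one pass."""
    b_n, c_n, ho, wo = g.shape
    k = w.shape[1]
    for b in range(b_n):
        for c in range(c_n):
            for y in range(ho):
                gr = g[b, c, y]
                yb = y * stride
                for i in range(k):
                    xr = xp[b, c, yb + i * dilation]
                    gxr = gxp[b, c, yb + i * dilation]
                    for j in range(k):
                        wv = w[c, i, j]
                        oj = j * dilation
                        acc = np.float32(0.0)
                        for x in range(wo):
                            acc += gr[x] * xr[oj + x * stride]
                        gw[c, i, j] += acc
                        for x in range(wo):
                            gxr[oj + x * stride] += gr[x] * wv
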