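"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

The engine is deliberately small: float32 tensors, a handful of primitives
(elementwise arithmetic, matmul, reductions, reshaping, concatenation,
2-D convolution with stride/dilation, bilinear resampling), and a
topological-sort backward pass.  It exists so the segmentation model and its
training loop are fully self-contained and deterministic on a single CPU.

Gradient propagation can be switched off globally (``no_grad``) for
inference, in which case no graph is recorded.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float32 array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()
        self.name = name

    # ---- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def zero_grad(self) -> None:
        self.grad = None

    # ---- graph plumbing ------------------------------------------------------
    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add `g` to the stored gradient; `own=True` promises `g` is a fresh
        float32 array the caller will not reuse, so it can be adopted."""
        if self.grad is None:
            if own and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _needs_grad(t: "Tensor") -> bool:
    return t.requires_grad or bool(t._parents)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---- elementwise -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if _needs_grad(a):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        if _needs_grad(b):
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** np.float32(exponent)

    def backward(g):
        a._accumulate(g * exponent * a.data ** np.float32(exponent - 1), own=True)

    return _make(data, (a,), backward)


def log(a, eps: float = 0.0) -> Tensor:
    """Natural logarithm; `eps` is added under the log for numeric safety."""
    a = _as_tensor(a)
    shifted = a.data + np.float32(eps)
    data = np.log(shifted)

    def backward(g):
        a._accumulate(g / shifted, own=True)

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data, own=True)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0), own=True)

    return _make(data, (a,), backward)


def relu6(a) -> Tensor:
    """min(max(0, x), 6) — the clipped rectifier used throughout MobileNetV2."""
    from . import _kernels
    a = _as_tensor(a)
    if a.data.ndim == 4 and a.data.flags.c_contiguous:
        data = np.empty_like(a.data)
        _kernels.relu6_fwd(a.data, data)

        def backward(g):
            gx = np.empty_like(data)
            _kernels.relu6_bwd(a.data, np.ascontiguousarray(g), gx)
            a._accumulate(gx, own=True)

        return _make(data, (a,), backward)

    data = np.minimum(np.maximum(a.data, 0), 6).astype(np.float32)

    def backward(g):
        a._accumulate(g * ((a.data > 0) & (a.data < 6)), own=True)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * data * (1.0 - data), own=True)

    return _make(data, (a,), backward)


# ---- reductions / shaping ----------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.broadcast_to(g, a.data.shape)
        a._accumulate(np.ascontiguousarray(grad), own=True)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(data, tensors, backward)


def crop2d(a, height: int, width: int) -> Tensor:
    """Keep the top-left `height`×`width` window of a B×C×H×W tensor."""
    a = _as_tensor(a)
    data = a.data[:, :, :height, :width]

    def backward(g):
        grad = np.zeros_like(a.data)
        grad[:, :, :height, :width] = g
        a._accumulate(grad, own=True)

    return _make(np.ascontiguousarray(data), (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if _needs_grad(a):
            a._accumulate(g @ b.data.T, own=True)
        if _needs_grad(b):
            b._accumulate(a.data.T @ g, own=True)

    return _make(data, (a, b), backward)


def softmax(a, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot), own=True)

    return _make(data, (a,), backward)


# ---- convolution -------------------------------------------------------------
# Layout convention: activations are C-contiguous NCHW; patch matrices are
# (B, C·k·k, Ho·Wo) so every conv is a batched GEMM with no transposes.

def _gemm_nchw(wmat: np.ndarray, col: np.ndarray, bias: Optional[Tensor],
               b: int, out_ch: int, ho: int, wo: int) -> np.ndarray:
    out3 = np.matmul(wmat, col)          # (O, K) @ (B, K, HW) -> (B, O, HW)
    if bias is not None:
        out3 += bias.data.reshape(1, out_ch, 1)
    return out3.reshape(b, out_ch, ho, wo)


def _conv1x1(x: Tensor, weight: Tensor, bias: Optional[Tensor], stride: int) -> Tensor:
    """Pointwise-convolution fast path: one batched channel-mixing GEMM."""
    b, c, h, w = x.data.shape
    out_ch = weight.data.shape[0]
    src = (np.ascontiguousarray(x.data[:, :, ::stride, ::stride]) if stride > 1
           else np.ascontiguousarray(x.data))
    _, _, ho, wo = src.shape
    x3 = src.reshape(b, c, ho * wo)
    wmat = weight.data.reshape(out_ch, c)
    data = _gemm_nchw(wmat, x3, bias, b, out_ch, ho, wo)

    def backward(g):
        g3 = np.ascontiguousarray(g).reshape(b, out_ch, ho * wo)
        weight._accumulate(np.matmul(g3, x3.transpose(0, 2, 1)).sum(axis=0)
                           .reshape(weight.data.shape), own=True)
        if bias is not None:
            bias._accumulate(g3.sum(axis=(0, 2)), own=True)
        if not _needs_grad(x):
            return
        gsrc = np.matmul(wmat.T, g3).reshape(b, c, ho, wo)
        if stride > 1:
            gx = np.zeros_like(x.data)
            gx[:, :, ::stride, ::stride] = gsrc
        else:
            gx = gsrc
        x._accumulate(gx, own=True)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, backward)


def _conv_center_tap(x: Tensor, weight: Tensor, bias: Optional[Tensor]) -> Tensor:
    """Degenerate dilated 3×3 conv == 1×1 conv with the kernel's center tap."""
    b, c, h, w = x.data.shape
    out_ch = weight.data.shape[0]
    x3 = np.ascontiguousarray(x.data).reshape(b, c, h * w)
    wmat = np.ascontiguousarray(weight.data[:, :, 1, 1])
    data = _gemm_nchw(wmat, x3, bias, b, out_ch, h, w)

    def backward(g):
        g3 = np.ascontiguousarray(g).reshape(b, out_ch, h * w)
        gw = np.zeros_like(weight.data)
        gw[:, :, 1, 1] = np.matmul(g3, x3.transpose(0, 2, 1)).sum(axis=0)
        weight._accumulate(gw, own=True)
        if bias is not None:
            bias._accumulate(g3.sum(axis=(0, 2)), own=True)
        if _needs_grad(x):
            x._accumulate(np.matmul(wmat.T, g3).reshape(b, c, h, w), own=True)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Dense 2-D cross-correlation. weight: (O, C, k, k); x: (B, C, H, W)."""
    from . import _kernels
    x, weight = _as_tensor(x), _as_tensor(weight)
    out_ch, in_ch, k, _ = weight.data.shape
    b, c, h, w = x.data.shape
    if c != in_ch:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {in_ch}")
    if k == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride)
    if (k == 3 and stride == 1 and padding == dilation
            and dilation >= h and dilation >= w):
        # Off-center taps of a heavily dilated kernel land entirely in the
        # zero padding: the layer is exactly its center-tap 1×1 convolution
        # (off-center weights see zero activations and zero gradient).
        return _conv_center_tap(x, weight, bias)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else np.ascontiguousarray(x.data)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - (k - 1) * dilation - 1) // stride + 1
    wo = (wp - (k - 1) * dilation - 1) // stride + 1
    col = np.empty((b, c * k * k, ho * wo), dtype=np.float32)
    _kernels.im2col(xp, k, stride, dilation, ho, col)
    wmat = weight.data.reshape(out_ch, c * k * k)
    data = _gemm_nchw(wmat, col, bias, b, out_ch, ho, wo)

    def backward(g):
        g3 = np.ascontiguousarray(g).reshape(b, out_ch, ho * wo)
        weight._accumulate(np.matmul(g3, col.transpose(0, 2, 1)).sum(axis=0)
                           .reshape(weight.data.shape), own=True)
        if bias is not None:
            bias._accumulate(g3.sum(axis=(0, 2)), own=True)
        if not _needs_grad(x):
            return
        gcol = np.matmul(wmat.T, g3)
        gxp = np.zeros_like(xp)
        _kernels.col2im(gcol, k, stride, dilation, ho, gxp)
        gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
        x._accumulate(gx, own=not padding)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, stride: int = 1,
                     padding: int = 0, dilation: int = 1) -> Tensor:
    """Per-channel (depthwise) 2-D convolution. weight: (C, 1, k, k)."""
    from . import _kernels
    x, weight = _as_tensor(x), _as_tensor(weight)
    c_w, _, k, _ = weight.data.shape
    b, c, h, w = x.data.shape
    if c != c_w:
        raise ValueError(f"depthwise_conv2d: {c} channels vs weight {c_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else np.ascontiguousarray(x.data)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - (k - 1) * dilation - 1) // stride + 1
    wo = (wp - (k - 1) * dilation - 1) // stride + 1
    wk = np.ascontiguousarray(weight.data.reshape(c, k, k))
    data = np.empty((b, c, ho, wo), dtype=np.float32)
    _kernels.depthwise_fwd(xp, wk, stride, dilation, data)

    def backward(g):
        gw = np.zeros((c, k, k), dtype=np.float32)
        gxp = np.zeros_like(xp)
        _kernels.depthwise_bwd(xp, wk, np.ascontiguousarray(g), stride, dilation,
                               gxp, gw)
        weight._accumulate(gw.reshape(weight.data.shape), own=True)
        if _needs_grad(x):
            gx = gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp
            x._accumulate(gx, own=not padding)

    return _make(data, (x, weight), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
               mean: Optional[np.ndarray] = None,
               var: Optional[np.ndarray] = None):
    """Fused per-channel normalization of a B×C×H×W tensor.

    With ``mean``/``var`` omitted, batch statistics are computed (training
    mode) and returned alongside the output for the layer's running-stat
    update; otherwise the given statistics are treated as constants
    (inference mode).
    """
    from . import _kernels
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    b, c, h, w = x.data.shape
    batch_stats = mean is None
    xd = np.ascontiguousarray(x.data)
    if batch_stats:
        mean = np.empty(c, np.float32)
        var = np.empty(c, np.float32)
        _kernels.channel_stats(xd, mean, var)
    inv_sigma = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = np.empty_like(xd)
    data = np.empty_like(xd)
    _kernels.bn_fwd(xd, gamma.data, beta.data, mean.astype(np.float32),
                    inv_sigma, xhat, data)

    def backward(g):
        g = np.ascontiguousarray(g)
        if batch_stats:
            dgamma = np.zeros(c, np.float32)
            dbeta = np.zeros(c, np.float32)
            gx = np.empty_like(g)
            _kernels.bn_bwd(g, xhat, gamma.data, inv_sigma, dgamma, dbeta, gx)
            gamma._accumulate(dgamma, own=True)
            beta._accumulate(dbeta, own=True)
            if _needs_grad(x):
                x._accumulate(gx, own=True)
        else:
            beta._accumulate(g.sum(axis=(0, 2, 3)), own=True)
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)), own=True)
            if _needs_grad(x):
                x._accumulate((gamma.data * inv_sigma).reshape(1, c, 1, 1) * g,
                              own=True)

    out = _make(data, (x, gamma, beta), backward)
    return out, mean, var


# ---- resampling --------------------------------------------------------------

def _linear_resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    mat[np.arange(n_out), lo] += 1 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of a B×C×H×W tensor to (H_out, W_out)."""
    x = _as_tensor(x)
    b, c, h, w = x.data.shape
    ho, wo = size
    rh = _linear_resize_matrix(ho, h)
    rw = _linear_resize_matrix(wo, w)
    # separable: rows then columns
    data = np.einsum("oh,bchw,pw->bcop", rh, x.data, rw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,bcop,pw->bchw", rh, g, rw, optimize=True),
                      own=True)

    return _make(np.ascontiguousarray(data), (x,), backward)


def pad2d(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the bottom/right of a B×C×H×W tensor."""
    x = _as_tensor(x)
    if pad_h == 0 and pad_w == 0:
        return x
    data = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))

    def backward(g):
        b, c, h, w = x.data.shape
        x._accumulate(g[:, :, :h, :w])

    return _make(data, (x,), backward)
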