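"""Optimizers for the NumPy autograd engine."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates.

    Defaults follow the common (beta1, beta2, eps) = (0.9, 0.999, 1e-8).
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        from . import _kernels
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            if not p.grad.flags.c_contiguous:
                p.grad = np.ascontiguousarray(p.grad)
            _kernels.adam_step(p.data.reshape(-1), p.grad.reshape(-1),
                               m.reshape(-1), v.reshape(-1), self.lr,
                               self.beta1, self.beta2, self.eps, float(self.t))
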