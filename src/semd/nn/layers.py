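"""Neural-network building blocks (modules) on top of the autograd engine.

Convolutions followed by batch normalization carry no bias; weights are
He-normal initialized from an explicit ``numpy.random.Generator`` so a run
seed fully determines the network.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    """Minimal module base: attribute-registered parameters and submodules."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf_name, buf in self._named_buffers():
            state[f"{name}{buf_name}"] = buf.copy()
        return state

    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                if isinstance(value, BatchNorm2d):
                    yield key + ".", "running_mean", value.running_mean
                    yield key + ".", "running_var", value.running_var
                yield from value._named_buffers(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        if isinstance(item, BatchNorm2d):
                            yield f"{key}.{i}.", "running_mean", item.running_mean
                            yield f"{key}.{i}.", "running_var", item.running_var
                        yield from item._named_buffers(f"{key}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        consumed = set()
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
            consumed.add(name)
        for prefix, buf_name, _ in self._named_buffers():
            key = f"{prefix}{buf_name}"
            if key in state:
                self._set_buffer(prefix, buf_name, np.asarray(state[key], dtype=np.float32))
                consumed.add(key)

    def _set_buffer(self, prefix: str, buf_name: str, arr: np.ndarray) -> None:
        obj: Module = self
        parts = prefix.rstrip(".").split(".")
        for part in parts:
            obj = vars(obj)[part] if not part.isdigit() else obj[int(part)]  # type: ignore
        setattr(obj, buf_name, arr.copy())


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.items = list(mods)

    def __getitem__(self, i: int) -> Module:
        return self.items[i]

    def __len__(self) -> int:
        return len(self.items)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(he_normal(rng, (channels, 1, kernel, kernel), kernel * kernel),
                             requires_grad=True)
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return T.depthwise_conv2d(x, self.weight, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = T.batch_norm(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            out, _, _ = T.batch_norm(x, self.gamma, self.beta, self.eps,
                                     self.running_mean, self.running_var)
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(he_normal(rng, (out_features, in_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, T.transpose(self.weight, (1, 0))) + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu6(x)
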