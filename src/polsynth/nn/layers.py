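"""Layers for the translation networks: convolutions, instance norm, linear."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "Linear", "InstanceNorm2d", "Sequential"]


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.astype(p.data.dtype, copy=True)

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def __call__(self, x):
        return self.forward(x)


def _collect(v):
    if isinstance(v, Tensor):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, dtype=np.float32):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        w = rng.uniform(-bound, bound, size=(in_features, out_features))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return T.add(T.matmul(x, self.weight), self.bias)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Statistics are always taken from the current sample (there is no
    running average), which is why the training batch size is fixed at 1.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones((1, n_ch, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_ch, 1, 1), dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = T.tmean(x, axis=(2, 3), keepdims=True)
        xc = T.add(x, T.mul(mu, -1.0))
        var = T.tmean(T.mul(xc, xc), axis=(2, 3), keepdims=True)
        y = T.div(xc, T.sqrt(T.add(var, self.eps)))
        return T.add(T.mul(y, self.gamma), self.beta)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x) if isinstance(m, Module) else m(x)
        return x
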