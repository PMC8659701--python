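"""Module/parameter containers built on the autograd Tensor."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and sub-modules by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                if id(v) not in seen:
                    params.append(v)
                    seen.add(id(v))
            elif isinstance(v, Module):
                for p in v.parameters():
                    if id(p) not in seen:
                        params.append(p)
                        seen.add(id(p))
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                params.append(p)
                                seen.add(id(p))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=p.data.dtype).reshape(p.data.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.weight = Tensor(_kaiming(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, din: int, dout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((din, dout), dtype=np.float32)
        else:
            w = _kaiming(rng, (din, dout), din)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(dout, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class GroupNorm(Module):
    """Group normalization; batch-size independent, good for batch=1 training."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        while channels % groups != 0:
            groups -= 1
        self.groups = max(groups, 1)
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        norm = (xg - mu) * ((var + self.eps) ** -0.5)
        norm = norm.reshape(n, c, h, w)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return norm * gamma + beta


class ConvBlock(Module):
    """Conv -> GroupNorm -> ReLU, the workhorse block of both networks."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 norm: bool = True):
        self.conv = Conv2d(cin, cout, k=k, stride=stride, dilation=dilation,
                           rng=rng)
        self.norm = GroupNorm(cout) if norm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.relu()
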