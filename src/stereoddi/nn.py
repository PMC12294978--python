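"""Minimal neural-network layer and optimizer primitives over `autodiff`.

Modules register parameters and submodules through attribute assignment, so
``module.parameters()`` and ``state_dict()`` work the way users of the large
deep-learning frameworks expect, at a fraction of the surface.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class with parameter / submodule registries and a training flag."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        object.__setattr__(self, key, value)

    def parameters(self) -> Iterator[Parameter]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = dict(self.named_parameters())
        missing = set(named) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def fan_in_uniform(rng: np.random.Generator, shape: tuple,
                   fan_in: int | None = None) -> np.ndarray:
    """Standard fan-in scaled uniform initialisation U(-1/sqrt(f), 1/sqrt(f))."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Parameter(fan_in_uniform(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(fan_in_uniform(rng, (out_dim,), in_dim)) if bias else None

    def __call__(self, x) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x) -> Tensor:
        x = ad.astensor(x)
        m = ad.tmean(x, axis=-1, keepdims=True)
        centered = ad.add(x, ad.mul(m, -1.0))
        var = ad.tmean(ad.power(centered, 2.0), axis=-1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(centered, inv), self.gamma), self.beta)


class AdamW:
    """AdamW with decoupled weight decay (the training optimizer)."""

    def __init__(self, params, lr: float = 5e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-3):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, t: int, total: int, warmup: int = 0) -> float:
    """Cosine-annealed learning rate over `total` epochs, no restarts,
    with an optional linear warmup over the first `warmup` epochs."""
    if warmup > 0 and t < warmup:
        return lr0 * (t + 1) / warmup
    if total <= 0:
        return lr0
    frac = min(max(t - warmup, 0), total - warmup) / max(total - warmup, 1)
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most `max_norm`."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm
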