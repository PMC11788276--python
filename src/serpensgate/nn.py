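"""Module system and elementary layers.

Parameter-accounting convention (used by every block in the package):

* :class:`Parameter` — trainable; counted in ``params_trainable`` and receives
  gradients.
* :class:`Buffer` — fixed, non-trainable values that are part of the model
  definition (the DFL expectation projection, the frozen 3x3 scatter/gather
  kernels of super-token attention); counted in ``params_fixed``.
* Batch-norm running statistics are bookkeeping, not parameters: they are kept
  as plain arrays and excluded from both counts. Scale and shift are trainable.
"""

from __future__ import annotations

import numpy as np

from .engine import Tensor, concat, conv2d, maxpool2d, upsample_nearest2


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Buffer(Tensor):
    """Fixed model constant, counted as a non-trainable parameter."""

    def __init__(self, data):
        super().__init__(data, requires_grad=False)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Buffer):
            self._buffers[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, v in self._params.items():
            yield prefix + k, v
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def named_buffers(self, prefix: str = ""):
        for k, v in self._buffers.items():
            yield prefix + k, v
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def buffers(self):
        return [b for _, b in self.named_buffers()]

    def num_params(self) -> tuple[int, int]:
        """(trainable, fixed) parameter counts."""
        return (sum(p.size for p in self.parameters()),
                sum(b.size for b in self.buffers()))

    def num_leaf_modules(self) -> int:
        """Leaf-module count (the granularity of 'layers' in model summaries)."""
        subs = list(self._modules.values())
        if not subs:
            return 1 if (self._params or self._buffers or not subs) else 0
        return sum(m.num_leaf_modules() for m in subs)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({"buf:" + k: v.data.copy() for k, v in self.named_buffers()})
        out.update({"stat:" + k: v.copy() for k, v in self._named_stats()})
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        stats = dict(self._named_stats())
        for k, v in sd.items():
            if k.startswith("buf:"):
                bufs[k[4:]].data[...] = v
            elif k.startswith("stat:"):
                stats[k[5:]][...] = v
            else:
                params[k].data[...] = v

    def _named_stats(self, prefix: str = ""):
        for k in getattr(self, "_stat_names", ()):
            yield prefix + k, getattr(self, k)
        for k, m in self._modules.items():
            yield from m._named_stats(prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


def autopad(k: int, p: int | None = None) -> int:
    return k // 2 if p is None else p


def kaiming(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


_default_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the global weight-initialisation stream (used by training runs)."""
    global _default_rng
    _default_rng = np.random.default_rng(seed)


class Conv2d(Module):
    """Plain 2-D convolution (optionally biased); no normalisation."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, bias: bool = True):
        super().__init__()
        if min(c1, c2, k, s) < 1:
            raise ValueError("conv config values must be positive integers")
        self.c1, self.c2, self.k, self.s, self.p = c1, c2, k, s, autopad(k, p)
        self.weight = Parameter(kaiming(_default_rng, (c2, c1, k, k)))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.s, padding=self.p)


class BatchNorm2d(Module):
    """Per-channel batch normalisation (trainable scale/shift, running stats)."""

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._stat_names = ("running_mean", "running_var")

    def forward(self, x):
        from .engine import batchnorm2d
        if self.training:
            y, mu, var = batchnorm2d(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return y
        y, _, _ = batchnorm2d(x, self.gamma, self.beta, self.eps,
                              self.running_mean, self.running_var)
        return y


class GroupNorm(Module):
    def __init__(self, groups: int, c: int, eps: float = 1e-5):
        super().__init__()
        if c % groups:
            raise ValueError(f"channels {c} not divisible by groups {groups}")
        self.groups, self.c, self.eps = groups, c, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))

    def forward(self, x):
        B, C, H, W = x.shape
        xg = x.reshape(B, self.groups, C // self.groups * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps) ** 0.5)).reshape(B, C, H, W)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class MaxPool2d(Module):
    def __init__(self, k: int, s: int = 1):
        super().__init__()
        self.k, self.s = k, s

    def forward(self, x):
        return maxpool2d(x, self.k, stride=self.s)


class Upsample2(Module):
    """Nearest-neighbour x2 upsampling (parameter-free)."""

    def forward(self, x):
        return upsample_nearest2(x)


class Concat(Module):
    """Channel concatenation of multiple inputs (parameter-free)."""

    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return concat(list(xs), axis=self.axis)


class SGD:
    """SGD with momentum and decoupled-style weight decay on the gradient."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # decay conv/linear weights only
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
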