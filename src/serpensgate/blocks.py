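"""Standard detector building blocks with exact parameter accounting.

Every block here obeys two contracts:

* a *shape law* — stride-2 convolutions halve the spatial extent (same
  padding), stride-1 odd-kernel pooling and the pyramid/attention blocks
  preserve it, nearest upsampling doubles it;
* a *count law* — ``count_params(block)`` returns exact (trainable, fixed)
  totals, computable without a forward pass. A "conv block" is a bias-free
  convolution (c_in*c_out*k^2 weights) + batch-norm scale and shift (2*c_out)
  + SiLU; batch-norm running statistics are not parameters.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .engine import Tensor, concat, softmax


class InvalidConfigError(ValueError):
    """Raised when a block is constructed with an inconsistent configuration."""


class ConvBlock(nn.Module):
    """Convolution + batch norm + SiLU; the ``Conv`` unit of the layer table."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None):
        super().__init__()
        if min(c1, c2, k, s) < 1:
            raise InvalidConfigError(
                f"conv block needs positive (c_in,c_out,k,s), got {(c1, c2, k, s)}")
        self.conv = nn.Conv2d(c1, c2, k, s, p, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.c1, self.c2 = c1, c2

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    """Two 3x3 conv blocks with an optional residual add."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, second=None):
        super().__init__()
        self.cv1 = ConvBlock(c1, c2, 3, 1)
        self.cv2 = second if second is not None else ConvBlock(c2, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Cross-stage-partial block: split, n bottlenecks, concat-all, fuse.

    Hidden width c = c_out/2; the fuse conv sees (2+n)*c channels.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 bottleneck_factory=None):
        super().__init__()
        if c2 % 2:
            raise InvalidConfigError(f"C2f output channels must be even, got {c2}")
        if n < 1:
            raise InvalidConfigError(f"C2f repeat count must be >= 1, got {n}")
        self.c = c2 // 2
        self.cv1 = ConvBlock(c1, 2 * self.c, 1, 1)
        make = bottleneck_factory or (lambda c: Bottleneck(c, c, shortcut))
        self.m = nn.ModuleList([make(self.c) for _ in range(n)])
        self.cv2 = ConvBlock((2 + n) * self.c, c2, 1, 1)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        ys = [a, b]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class SPPELAN(nn.Module):
    """Spatial pyramid pooling with ELAN-style multi-branch aggregation.

    1x1 conv to the pyramid width, three cascaded 5x5 stride-1 max pools
    (each pooling the previous stage), 4-way concat, 1x1 fuse. Shape-preserving.
    """

    def __init__(self, c1: int, c2: int, c3: int):
        super().__init__()
        if min(c1, c2, c3) < 1:
            raise InvalidConfigError(
                f"SPPELAN needs positive channel counts, got {(c1, c2, c3)}")
        self.cv1 = ConvBlock(c1, c3, 1, 1)
        self.pools = nn.ModuleList([nn.MaxPool2d(5, 1) for _ in range(3)])
        self.cv5 = ConvBlock(4 * c3, c2, 1, 1)

    def forward(self, x):
        ys = [self.cv1(x)]
        for pool in self.pools:
            ys.append(pool(ys[-1]))
        return self.cv5(concat(ys, axis=1))


class DFL(nn.Module):
    """Distribution-focal projection: per-side bin distribution -> offset.

    Holds a single fixed (non-trainable) vector of the bin indices
    0..reg_max-1; the expected offset is the softmax-weighted sum.
    """

    def __init__(self, reg_max: int = 16):
        super().__init__()
        self.reg_max = reg_max
        self.proj = nn.Buffer(np.arange(reg_max, dtype=np.float32))

    def forward(self, dist: Tensor) -> Tensor:
        """dist: (..., reg_max) bin logits -> (...) expected offset."""
        p = softmax(dist, axis=-1)
        return (p * self.proj.reshape(*([1] * (dist.ndim - 1)), self.reg_max)).sum(axis=-1)


class Detect(nn.Module):
    """Decoupled anchor-free detection head over three feature scales.

    Per scale: a box branch (two 3x3 conv blocks at width c2, biased 1x1 conv
    to 4*reg_max bin logits) and a class branch (two 3x3 conv blocks at width
    c3, biased 1x1 conv to nc class logits), plus one shared fixed DFL
    projection.
    """

    def __init__(self, nc: int, ch: tuple[int, ...], reg_max: int = 16):
        super().__init__()
        ch = tuple(ch)
        if not ch:
            raise InvalidConfigError("detect head needs at least one input scale")
        if nc < 1:
            raise InvalidConfigError(f"class count must be >= 1, got {nc}")
        self.nc, self.ch, self.reg_max = nc, ch, reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_branches = nn.ModuleList([
            nn.Sequential([ConvBlock(c, c2, 3), ConvBlock(c2, c2, 3),
                           nn.Conv2d(c2, 4 * reg_max, 1, bias=True)])
            for c in ch])
        self.cls_branches = nn.ModuleList([
            nn.Sequential([ConvBlock(c, c3, 3), ConvBlock(c3, c3, 3),
                           nn.Conv2d(c3, nc, 1, bias=True)])
            for c in ch])
        self.dfl = DFL(reg_max)

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        """Raw per-scale maps (B, 4*reg_max + nc, H, W); decoding is separate."""
        return [concat([bb(x), cb(x)], axis=1)
                for x, bb, cb in zip(xs, self.box_branches, self.cls_branches)]


class Upsample(nn.Upsample2):
    pass


class Concat(nn.Concat):
    pass


# ---------------------------------------------------------------------------
# factory + audit API
# ---------------------------------------------------------------------------

def build_conv_block(c_in: int, c_out: int, k: int, s: int) -> ConvBlock:
    return ConvBlock(c_in, c_out, k, s)


def build_c2f(c_in: int, c_out: int, n: int = 1, shortcut: bool = False) -> C2f:
    return C2f(c_in, c_out, n, shortcut)


def build_sppelan(c_in: int, c_out: int, c_mid: int) -> SPPELAN:
    return SPPELAN(c_in, c_out, c_mid)


def build_detect_head(nc: int, ch, reg_max: int = 16) -> Detect:
    return Detect(nc, ch, reg_max)


def count_params(block: nn.Module) -> tuple[int, int]:
    """(trainable, fixed) parameter counts of any block, by exact summation."""
    return block.num_params()
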