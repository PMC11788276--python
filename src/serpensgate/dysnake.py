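"""Dynamic snake convolution: deformable sampling along a continuous path.

A snake kernel is a straight axis-aligned line of k sampling points that is
perturbed by learned, tanh-bounded offsets. The perturbation is *continuity
constrained*: coordinates are accumulated from the kernel centre outward, so
each sampling point references its neighbour and can never jump more than one
extra pixel per step. Two morphologies exist — ``x`` (the kernel extends along
the image width) and ``y`` (along the height).

Offsets carry two components per kernel position: an *elastic* component that
stretches or compresses the step along the morph axis, and a *drift* component
accumulated on the perpendicular axis, letting the path bend to follow
elongated, twisted lesion structures.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import Bottleneck, C2f, ConvBlock, InvalidConfigError
from .engine import Tensor, bilinear_sample, concat


class OffsetPredictor(nn.Module):
    """3x3 convolution + batch norm + tanh producing 2k bounded offsets.

    Output layout: channels [0:k] are the elastic (morph-axis) offsets, channels
    [k:2k] the perpendicular drift offsets, each strictly inside (-1, 1).
    """

    def __init__(self, c_in: int, k: int):
        super().__init__()
        if k % 2 == 0 or k < 3:
            raise InvalidConfigError(f"snake kernel length must be odd >= 3, got {k}")
        self.k = k
        self.conv = nn.Conv2d(c_in, 2 * k, 3, 1, 1, bias=False)
        self.bn = nn.BatchNorm2d(2 * k)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).tanh()


def compute_offsets(features: Tensor, k: int,
                    predictor: OffsetPredictor | None = None) -> Tensor:
    """Offset field (B, 2k, H, W) for `features`; builds a fresh predictor if
    none is supplied (deterministic given the predictor's weights)."""
    if predictor is None:
        predictor = OffsetPredictor(features.shape[1], k)
    elif predictor.k != k:
        raise InvalidConfigError(f"predictor built for k={predictor.k}, asked k={k}")
    return predictor(features)


def snake_coordinates(offsets: Tensor, morph: str, H: int, W: int
                      ) -> tuple[Tensor, Tensor]:
    """Absolute sampling coordinates (ys, xs), each (B, k, H, W).

    The centre position coincides with the output pixel. Moving outward from
    the centre, the morph-axis coordinate advances by ``1 + elastic`` per step
    and the perpendicular coordinate accumulates the drift offsets, giving a
    continuous snake path.
    """
    if morph not in ("x", "y"):
        raise InvalidConfigError(f"morph must be 'x' or 'y', got {morph!r}")
    B, two_k, Hf, Wf = offsets.shape
    k = two_k // 2
    c = k // 2
    elastic = [offsets[:, i:i + 1] for i in range(k)]
    drift = [offsets[:, k + i:k + i + 1] for i in range(k)]
    zero = Tensor(np.zeros((B, 1, Hf, Wf), dtype=np.float32))
    u: list[Tensor | None] = [None] * k   # morph-axis relative coordinate
    v: list[Tensor | None] = [None] * k   # perpendicular relative coordinate
    u[c], v[c] = zero, zero
    for j in range(c + 1, k):
        u[j] = u[j - 1] + 1.0 + elastic[j]
        v[j] = v[j - 1] + drift[j]
    for j in range(c - 1, -1, -1):
        u[j] = u[j + 1] - 1.0 - elastic[j]
        v[j] = v[j + 1] + drift[j]
    us = concat(u, axis=1)
    vs = concat(v, axis=1)
    gy = Tensor(np.arange(H, dtype=np.float32).reshape(1, 1, H, 1))
    gx = Tensor(np.arange(W, dtype=np.float32).reshape(1, 1, 1, W))
    if morph == "x":
        return gy + vs, gx + us
    return gy + us, gx + vs


class DSConv(nn.Module):
    """One snake-convolution branch of a fixed morphology.

    Predict offsets, lay the snake path, bilinearly sample the k points per
    output pixel, then apply a k-point convolution over the sampled stack
    (equivalently a 1x1 convolution over C*k stacked channels), followed by
    group normalisation and SiLU. Shape-preserving for any input size.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, morph: str = "x"):
        super().__init__()
        if morph not in ("x", "y"):
            raise InvalidConfigError(f"morph must be 'x' or 'y', got {morph!r}")
        self.k, self.morph = k, morph
        self.offset = OffsetPredictor(c_in, k)
        self.conv = nn.Conv2d(c_in * k, c_out, 1, bias=False)
        self.gn = nn.GroupNorm(max(1, c_out // 4) if c_out % 4 == 0 else 1, c_out)

    def sample(self, x: Tensor) -> Tensor:
        """(B, C*k, H, W) stack of snake samples."""
        B, C, H, W = x.shape
        ys, xs = snake_coordinates(self.offset(x), self.morph, H, W)
        s = bilinear_sample(x, ys, xs)           # (B, C, k, H, W)
        return s.reshape(B, C * self.k, H, W)

    def forward(self, x: Tensor) -> Tensor:
        return self.gn(self.conv(self.sample(x))).silu()


class DySnakeConv(nn.Module):
    """Three-branch dynamic snake block: standard kxk conv block, a morph-x and
    a morph-y snake conv, concatenated and fused back by a 1x1 conv block."""

    def __init__(self, c_in: int, c_out: int, k: int = 3):
        super().__init__()
        if k % 2 == 0:
            raise InvalidConfigError(f"kernel length must be odd, got {k}")
        self.std = ConvBlock(c_in, c_out, k, 1)
        self.snake_x = DSConv(c_in, c_out, k, morph="x")
        self.snake_y = DSConv(c_in, c_out, k, morph="y")
        self.fuse = ConvBlock(3 * c_out, c_out, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = concat([self.std(x), self.snake_x(x), self.snake_y(x)], axis=1)
        return self.fuse(y)


def build_dysnakeconv(c_in: int, c_out: int, k: int = 3) -> DySnakeConv:
    return DySnakeConv(c_in, c_out, k)


class C2fDySnake(C2f):
    """C2f whose bottlenecks use a DySnakeConv as the second convolution.

    Accepts any input spatial size (the snake sampler adapts its coordinate
    grid to the incoming feature map).
    """

    def __init__(self, c_in: int, c_out: int, shortcut: bool = True, n: int = 1,
                 k: int = 3):
        super().__init__(
            c_in, c_out, n, shortcut,
            bottleneck_factory=lambda c: Bottleneck(
                c, c, shortcut, second=DySnakeConv(c, c, k)))


def build_c2f_dysnake(c_in: int, c_out: int, shortcut: bool = True) -> C2fDySnake:
    return C2fDySnake(c_in, c_out, shortcut)
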