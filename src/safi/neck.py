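"""PAN-FPN neck, with an optional grouped multi-kernel (ELC) convolution
replacing the second convolution of each bottleneck.

The ELC module splits its input into four channel groups, convolves them
with 1x1 / 3x3 / 5x5 / 7x7 kernels, concatenates, and mixes the groups with
a pointwise convolution, keeping output channels equal to input channels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import FeaturePyramid
from .blocks import C2f, ConvBlock
from .nn import concat

__all__ = [
    "ElcSpec", "ElcCostSpec", "ELCConv", "elc_cost",
    "BottleneckELC", "C2fELC", "PanNeck",
]

ELC_KERNELS = (1, 3, 5, 7)


@dataclass(frozen=True)
class ElcSpec:
    in_channels: int
    group_kernels: tuple = ELC_KERNELS

    def __post_init__(self):
        if self.in_channels % 4:
            raise ValueError(
                f"ELC requires channels divisible by 4, got {self.in_channels}"
            )
        if tuple(self.group_kernels) != ELC_KERNELS:
            raise ValueError(f"group kernels are fixed at {ELC_KERNELS}")

    @property
    def group_in(self) -> int:
        return self.in_channels // 4

    @property
    def group_out(self) -> int:
        # channel-preserving groups: concatenation restores in_channels
        return self.in_channels // 4


@dataclass(frozen=True)
class ElcCostSpec:
    """Operands of the convolution-cost comparison.

    k: kernel size of the reference standard convolution over 4c -> 4n
    channels; c, n: per-group input/output channels; x, y: output width and
    height of the feature map.
    """

    k: int
    c: int
    n: int
    x: int
    y: int

    def __post_init__(self):
        for name in ("k", "c", "n", "x", "y"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def elc_cost(spec: ElcCostSpec, include_pointwise: bool = False):
    """Multiply-accumulate counts of standard vs grouped multi-kernel conv.

    Returns (C1, C2, ratio) where C1 = k^2 * 4c * 4n * x * y is the standard
    convolution cost and C2 = (1^2+3^2+5^2+7^2) * c * n * x * y = 84*c*n*x*y
    is the grouped stage's cost.  The printed 1.7x ratio at k=3 excludes the
    pointwise mixing conv; pass include_pointwise=True to add its
    (4c*4n*x*y) term to C2.
    """
    area = spec.x * spec.y
    c1 = spec.k * spec.k * 4 * spec.c * 4 * spec.n * area
    c2 = sum(k * k for k in ELC_KERNELS) * spec.c * spec.n * area
    if include_pointwise:
        c2 += 4 * spec.c * 4 * spec.n * area
    return c1, c2, c1 / c2


class ELCConv(nn.Module):
    """Four-group multi-kernel convolution with pointwise group mixing."""

    def __init__(self, spec_or_channels, rng=None):
        super().__init__()
        spec = (spec_or_channels if isinstance(spec_or_channels, ElcSpec)
                else ElcSpec(spec_or_channels))
        self.spec = spec
        c = spec.group_in
        self.groups = nn.Sequential(
            *[ConvBlock(c, spec.group_out, k, rng=rng) for k in ELC_KERNELS]
        )
        self.mix = ConvBlock(4 * spec.group_out, spec.in_channels, 1, rng=rng)

    def forward(self, x):
        cin = x.shape[1]
        if cin != self.spec.in_channels:
            raise ValueError(
                f"ELC configured for {self.spec.in_channels} channels, got {cin}"
            )
        c = self.spec.group_in
        outs = [conv(x[:, i * c : (i + 1) * c]) for i, conv in enumerate(self.groups)]
        return self.mix(concat(outs, axis=1))


class BottleneckELC(nn.Module):
    """Bottleneck with its second convolution replaced by the ELC module."""

    def __init__(self, cin, cout, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBlock(cin, cout, 3, rng=rng)
        self.cv2 = ELCConv(cout, rng=rng)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2fELC(C2f):
    bottleneck_cls = BottleneckELC


def _c2f(use_elc):
    return C2fELC if use_elc else C2f


class PanNeck(nn.Module):
    """Top-down + bottom-up fusion over a three-level pyramid.

    in_channels: backbone tap widths; out_channels: the three fused output
    widths handed to the head.
    """

    def __init__(self, in_channels=(64, 128, 256), out_channels=(64, 128, 256),
                 use_elc=False, rng=None):
        super().__init__()
        t3, t4, t5 = in_channels
        n3, n4, n5 = out_channels
        block = _c2f(use_elc)
        self.in_channels = tuple(in_channels)
        self.out_channels = tuple(out_channels)
        self.up = nn.Upsample2x()
        self.td1 = block(t5 + t4, n4, 1, rng=rng)       # P5 up + P4
        self.td2 = block(n4 + t3, n3, 1, rng=rng)       # -> out P3
        self.down1 = ConvBlock(n3, n3, 3, 2, rng=rng)
        self.bu1 = block(n3 + n4, n4, 1, rng=rng)       # -> out P4
        self.down2 = ConvBlock(n4, n4, 3, 2, rng=rng)
        self.bu2 = block(n4 + t5, n5, 1, rng=rng)       # -> out P5

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        p3, p4, p5 = pyr.as_list()
        if (p3.shape[1], p4.shape[1], p5.shape[1]) != self.in_channels:
            raise ValueError(
                f"neck expects channels {self.in_channels}, got "
                f"{(p3.shape[1], p4.shape[1], p5.shape[1])}"
            )
        t4 = self.td1(concat([self.up(p5), p4], axis=1))
        o3 = self.td2(concat([self.up(t4), p3], axis=1))
        o4 = self.bu1(concat([self.down1(o3), t4], axis=1))
        o5 = self.bu2(concat([self.down2(o4), p5], axis=1))
        return FeaturePyramid(o3, o4, o5)
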