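"""Shared convolution blocks of the YOLOv8-style detector family."""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, concat


class ConvBlock(nn.Module):
    """Conv + BatchNorm + SiLU (no conv bias; the norm absorbs it)."""

    def __init__(self, cin, cout, k=1, s=1, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, s, groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """Two 3x3 convs with optional residual shortcut."""

    def __init__(self, cin, cout, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBlock(cin, cout, 3, rng=rng)
        self.cv2 = ConvBlock(cout, cout, 3, rng=rng)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Cross-stage block: split, chained bottlenecks, dense concat, fuse."""

    bottleneck_cls = Bottleneck

    def __init__(self, cin, cout, n=1, shortcut=False, rng=None):
        super().__init__()
        self.c = cout // 2
        self.cv1 = ConvBlock(cin, 2 * self.c, 1, rng=rng)
        self.blocks = nn.Sequential(
            *[self.bottleneck_cls(self.c, self.c, shortcut, rng=rng) for _ in range(n)]
        )
        self.cv2 = ConvBlock((2 + n) * self.c, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c :]]
        for b in self.blocks:
            parts.append(b(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, cin, cout, k=5, rng=None):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBlock(cin, c_, 1, rng=rng)
        self.cv2 = ConvBlock(c_ * 4, cout, 1, rng=rng)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(concat(y, axis=1))
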