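"""Feature-extraction backbones emitting a stride-8/16/32 pyramid.

Two interchangeable backbones are provided: the stock DarkNet-style C2f
backbone of the YOLOv8-n baseline, and the lightweight star-block backbone.
The star backbone follows the classic four-stage layered layout — channel
count doubling at each stage, channel expansion factor four inside blocks,
convolutional stride-2 downsampling — with stage widths/depths kept as
calibrated repository constants (they are not published; only the aggregate
parameter/FLOP budget of the assembled detector constrains them).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import C2f, ConvBlock, SPPF
from .nn import Tensor

__all__ = [
    "StarBlockSpec", "BackboneConfig", "FeaturePyramid",
    "StarBlock", "StarNetBackbone", "DarknetBackbone",
    "STAR_BACKBONE_CONFIG",
]


@dataclass(frozen=True)
class StarBlockSpec:
    """Configuration of one star block."""

    dim: int
    expansion: int = 4
    dw_kernel: int = 5
    use_residual: bool = True

    def __post_init__(self):
        if self.expansion != 4:
            raise ValueError("channel expansion factor is fixed at four")
        if self.dw_kernel % 2 == 0:
            raise ValueError("dw_kernel must be odd")
        if self.dim < 1:
            raise ValueError("dim must be positive")


@dataclass(frozen=True)
class BackboneConfig:
    """Four-stage star backbone layout (calibrated constants live in YAML)."""

    stem_channels: int = 8
    stage_channels: tuple = (16, 32, 64, 128)
    stage_depths: tuple = (2, 8, 2, 2)
    dw_kernel: int = 5
    out_stages: tuple = (1, 2, 3)  # -> strides 8, 16, 32
    use_sppf: bool = True

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.stage_depths) != 4:
            raise ValueError("exactly four stages are required")
        for a, b in zip(self.stage_channels, self.stage_channels[1:]):
            if b != 2 * a:
                raise ValueError(
                    f"stage channels must double at each stage, got {self.stage_channels}"
                )
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("stage depths must be positive")
        if tuple(self.out_stages) != (1, 2, 3):
            raise ValueError("pyramid taps must be the stride-8/16/32 stages")

    @property
    def out_channels(self) -> tuple:
        return tuple(self.stage_channels[i] for i in self.out_stages)


STAR_BACKBONE_CONFIG = BackboneConfig()


@dataclass
class FeaturePyramid:
    """Three feature maps at strides 8 / 16 / 32."""

    p3: Tensor
    p4: Tensor
    p5: Tensor

    def as_list(self):
        return [self.p3, self.p4, self.p5]

    @property
    def channels(self):
        return tuple(p.shape[1] for p in self.as_list())


def check_input_size(h: int, w: int, allow_resize: bool = False):
    if h % 32 or w % 32:
        if not allow_resize:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")
        return (h + 31) // 32 * 32, (w + 31) // 32 * 32
    return h, w


class StarBlock(nn.Module):
    """dw-conv -> two parallel 1x1 expansions -> gated product -> 1x1
    projection -> dw-conv -> batch norm -> residual.

    Batch statistics (not layer statistics) normalise the output of the
    final depthwise convolution.  One multiplicative branch passes through
    a bounded activation (ReLU6)."""

    def __init__(self, spec: StarBlockSpec, rng=None):
        super().__init__()
        d, e, k = spec.dim, spec.expansion, spec.dw_kernel
        self.spec = spec
        self.dw1 = ConvBlock(d, d, k, 1, groups=d, act=False, rng=rng)
        self.f1 = nn.Conv2d(d, e * d, 1, bias=True, rng=rng)
        self.f2 = nn.Conv2d(d, e * d, 1, bias=True, rng=rng)
        self.act = nn.ReLU6()
        self.g = nn.Conv2d(e * d, d, 1, bias=True, rng=rng)
        self.dw2 = nn.Conv2d(d, d, k, 1, groups=d, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(d)
        self.use_residual = spec.use_residual

    def forward(self, x):
        if x.shape[1] != self.spec.dim:
            raise ValueError(
                f"star block configured for {self.spec.dim} channels, got {x.shape[1]}"
            )
        y = self.dw1(x)
        y = self.act(self.f1(y)) * self.f2(y)
        y = self.bn2(self.dw2(self.g(y)))
        return x + y if self.use_residual else y


class StarNetBackbone(nn.Module):
    def __init__(self, cfg: BackboneConfig = STAR_BACKBONE_CONFIG, rng=None):
        super().__init__()
        self.cfg = cfg
        self.stem = ConvBlock(3, cfg.stem_channels, 3, 2, rng=rng)
        stages = []
        prev = cfg.stem_channels
        for c, depth in zip(cfg.stage_channels, cfg.stage_depths):
            layers = [ConvBlock(prev, c, 3, 2, rng=rng)]
            spec = StarBlockSpec(dim=c, dw_kernel=cfg.dw_kernel)
            layers += [StarBlock(spec, rng=rng) for _ in range(depth)]
            stages.append(nn.Sequential(*layers))
            prev = c
        self.stages = nn.Sequential(*stages)
        self.sppf = SPPF(prev, prev, rng=rng) if cfg.use_sppf else nn.Identity()

    @property
    def out_channels(self):
        return self.cfg.out_channels

    def forward(self, x) -> FeaturePyramid:
        check_input_size(x.shape[2], x.shape[3])
        x = self.stem(x)
        taps = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in self.cfg.out_stages:
                taps.append(x)
        taps[-1] = self.sppf(taps[-1])
        return FeaturePyramid(*taps)


class DarknetBackbone(nn.Module):
    """Stock YOLOv8-n backbone (nano scale: widths 16..256, C2f depths 1/2/2/1)."""

    def __init__(self, rng=None):
        super().__init__()
        self.stem = ConvBlock(3, 16, 3, 2, rng=rng)
        self.down1 = ConvBlock(16, 32, 3, 2, rng=rng)
        self.c2f1 = C2f(32, 32, 1, shortcut=True, rng=rng)
        self.down2 = ConvBlock(32, 64, 3, 2, rng=rng)
        self.c2f2 = C2f(64, 64, 2, shortcut=True, rng=rng)
        self.down3 = ConvBlock(64, 128, 3, 2, rng=rng)
        self.c2f3 = C2f(128, 128, 2, shortcut=True, rng=rng)
        self.down4 = ConvBlock(128, 256, 3, 2, rng=rng)
        self.c2f4 = C2f(256, 256, 1, shortcut=True, rng=rng)
        self.sppf = SPPF(256, 256, rng=rng)

    out_channels = (64, 128, 256)

    def forward(self, x) -> FeaturePyramid:
        check_input_size(x.shape[2], x.shape[3])
        x = self.c2f1(self.down1(self.stem(x)))
        p3 = self.c2f2(self.down2(x))
        p4 = self.c2f3(self.down3(p3))
        p5 = self.sppf(self.c2f4(self.down4(p4)))
        return FeaturePyramid(p3, p4, p5)
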