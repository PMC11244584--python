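"""Detection heads: the stock per-level head and the lightweight shared one.

The shared head (``DetectELHead``) applies one convolution tower — the same
weight objects — to every pyramid level, normalises with group statistics,
and scales each level's regression output with a learnable per-level scalar.
Both heads are anchor-free with distribution-based ("binned") box regression
decoded by expectation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeaturePyramid
from .blocks import ConvBlock
from .nn import Tensor, concat, softmax

__all__ = [
    "HeadSpec", "RawPrediction", "DetectHead", "DetectELHead",
    "decode_predictions", "nms", "dfl_expectation",
]

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class HeadSpec:
    num_classes: int = 2
    in_channels: tuple = (64, 128, 256)
    shared_channels: int = 40      # width of the shared tower
    shared_depth: int = 2          # 3x3 convs in the shared tower
    norm_groups: int = 8
    reg_bins: int = 16

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.reg_bins < 1:
            raise ValueError("reg_bins must be >= 1")
        if self.shared_channels % self.norm_groups:
            raise ValueError("shared_channels must be divisible by norm_groups")


@dataclass
class RawPrediction:
    """Per-level classification logits and box-regression maps."""

    cls: list          # each (N, num_classes, H, W)
    reg: list          # each (N, 4*reg_bins, H, W)
    strides: tuple = STRIDES
    reg_bins: int = 16

    @property
    def num_levels(self):
        return len(self.cls)


class _GNConv(nn.Module):
    """3x3 conv + group-statistic normalisation + SiLU."""

    def __init__(self, cin, cout, k, groups, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, bias=False, rng=rng)
        self.gn = nn.GroupNorm(groups, cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.gn(self.conv(x)))


class DetectHead(nn.Module):
    """Stock per-level head: independent reg/cls towers on every level."""

    def __init__(self, spec: HeadSpec = HeadSpec(), rng=None):
        super().__init__()
        self.spec = spec
        nc, ch = spec.num_classes, spec.in_channels
        reg_max = spec.reg_bins
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        reg_branches, cls_branches = [], []
        for c in ch:
            reg_branches.append(nn.Sequential(
                ConvBlock(c, c2, 3, rng=rng), ConvBlock(c2, c2, 3, rng=rng),
                nn.Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng)))
            cls_branches.append(nn.Sequential(
                ConvBlock(c, c3, 3, rng=rng), ConvBlock(c3, c3, 3, rng=rng),
                nn.Conv2d(c3, nc, 1, bias=True, rng=rng)))
        self.reg_branches = nn.Sequential(*reg_branches)
        self.cls_branches = nn.Sequential(*cls_branches)
        for branch, stride in zip(reg_branches, STRIDES):
            branch[-1].bias.data[:] = 1.0
        for branch, stride in zip(cls_branches, STRIDES):
            # prior: ~5 positives per 640-image at each level
            branch[-1].bias.data[:] = math.log(5 / nc / (640 / stride) ** 2)

    def forward(self, pyr: FeaturePyramid) -> RawPrediction:
        cls, reg = [], []
        for p, rb, cb in zip(pyr.as_list(), self.reg_branches, self.cls_branches):
            reg.append(rb(p))
            cls.append(cb(p))
        return RawPrediction(cls=cls, reg=reg, reg_bins=self.spec.reg_bins)


class DetectELHead(nn.Module):
    """Shared-convolution head with per-level adapters and Scale factors."""

    def __init__(self, spec: HeadSpec = HeadSpec(), rng=None):
        super().__init__()
        self.spec = spec
        nc, ch, c = spec.num_classes, spec.in_channels, spec.shared_channels
        g = spec.norm_groups
        adapters = []
        for cin in ch:
            if cin % 4:
                raise ValueError(f"head input channels must align, got {cin}")
            adapters.append(_GNConv(cin, c, 1, g, rng=rng))
        self.adapters = nn.Sequential(*adapters)
        # one shared tower: the SAME weight objects run on all three levels
        self.tower = nn.Sequential(
            *[_GNConv(c, c, 3, g, rng=rng) for _ in range(spec.shared_depth)])
        self.reg_out = nn.Conv2d(c, 4 * spec.reg_bins, 1, bias=True, rng=rng)
        self.cls_out = nn.Conv2d(c, nc, 1, bias=True, rng=rng)
        self.reg_out.bias.data[:] = 1.0
        self.cls_out.bias.data[:] = math.log(5 / nc / (640 / 16) ** 2)
        self.scales = nn.Sequential(*[nn.Scale(1.0) for _ in ch])

    def forward(self, pyr: FeaturePyramid) -> RawPrediction:
        cls, reg = [], []
        for p, adapter, scale in zip(pyr.as_list(), self.adapters, self.scales):
            t = self.tower(adapter(p))
            reg.append(scale(self.reg_out(t)))   # Scale touches regression only
            cls.append(self.cls_out(t))
        return RawPrediction(cls=cls, reg=reg, reg_bins=self.spec.reg_bins)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def anchor_points(shapes, strides=STRIDES, offset=0.5):
    """Cell-centre coordinates (in pixels) and per-anchor strides."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strs)


def dfl_expectation(reg: np.ndarray, reg_bins: int) -> np.ndarray:
    """Decode binned side distributions to expected distances (l, t, r, b).

    reg: (..., 4*reg_bins) logits. Returns (..., 4) distances in stride units.
    """
    x = reg.reshape(*reg.shape[:-1], 4, reg_bins)
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=-1, keepdims=True)
    return p @ np.arange(reg_bins, dtype=p.dtype)


def _flatten_raw(raw: RawPrediction):
    """-> cls (N, A, nc), reg (N, A, 4*bins), anchor pts (A,2), strides (A,)."""
    shapes = [c.shape[2:] for c in raw.cls]
    pts, strs = anchor_points(shapes, raw.strides)
    cls = np.concatenate(
        [c.data.reshape(c.shape[0], c.shape[1], -1).transpose(0, 2, 1) for c in raw.cls], axis=1)
    reg = np.concatenate(
        [r.data.reshape(r.shape[0], r.shape[1], -1).transpose(0, 2, 1) for r in raw.reg], axis=1)
    return cls, reg, pts, strs


def decoded_boxes(raw: RawPrediction):
    """Decode every anchor to an xyxy box (numpy, no gradients)."""
    cls, reg, pts, strs = _flatten_raw(raw)
    dist = dfl_expectation(reg, raw.reg_bins) * strs[None, :, None]
    x1y1 = pts[None] - dist[..., :2]
    x2y2 = pts[None] + dist[..., 2:]
    return np.concatenate([x1y1, x2y2], axis=-1), cls


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (K,4) xyxy boxes."""
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices.

    Ties in score are broken deterministically by box area then coordinates.
    """
    if len(boxes) == 0:
        return np.empty(0, dtype=int)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    order = np.lexsort((boxes[:, 1], boxes[:, 0], -areas, -scores))
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        suppressed[idx] = True
        rest = order[~suppressed[order]]
        if len(rest):
            ious = box_iou_matrix(boxes[idx : idx + 1], boxes[rest])[0]
            suppressed[rest[ious > iou_thresh]] = True
    return np.array(keep, dtype=int)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode_predictions(raw: RawPrediction, conf_thresh: float = 0.25,
                       iou_thresh: float = 0.7, image_size=None):
    """Raw maps -> per-image list of (class_id, score, x1, y1, x2, y2).

    Class-wise NMS; boxes clipped to ``image_size`` (w, h) when given.
    """
    if not (0 <= conf_thresh <= 1 and 0 <= iou_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    boxes_all, cls_all = decoded_boxes(raw)
    n, _, nc = cls_all.shape
    results = []
    for i in range(n):
        scores = _stable_sigmoid(cls_all[i])
        dets = []
        for c in range(nc):
            sc = scores[:, c]
            m = sc >= conf_thresh
            if not m.any():
                continue
            bx, sc = boxes_all[i][m], sc[m]
            if image_size is not None:
                w, h = image_size
                bx = np.clip(bx, 0, [w, h, w, h])
            valid = (bx[:, 2] > bx[:, 0]) & (bx[:, 3] > bx[:, 1])
            bx, sc = bx[valid], sc[valid]
            for k in nms(bx, sc, iou_thresh):
                dets.append((c, float(sc[k]), *map(float, bx[k])))
        dets.sort(key=lambda d: -d[1])
        results.append(dets)
    return results
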