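"""Bounding-box regression losses and the composite detection loss.

The box-loss family implemented here subtracts a penalty transform from IoU:

    P    = mean of the four target-normalised corresponding-edge distances
    f(P) = 1 - exp(-P^2)
    PIoU = IoU - f(P),            -1 <= PIoU <= 1
    L    = 1 - PIoU,               0 <= L   <= 2
    q    = exp(-P),                q in (0, 1]
    u(x) = 3x * exp(-x^2)
    Lv2  = u(lambda * q) * L

The penalty factor's explicit form is not printed alongside the loss
equations in the originating work; the form above (corresponding-edge
distances normalised by target width/height, averaged) follows the cited
reference and satisfies the stated anchor property P = 0 iff the boxes
coincide (q = 1).

Scalar reference implementations operate on ``BoxPair`` (numpy, exact);
batched autograd versions power training.  CIoU is provided as the
baseline ablation arm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, bce_with_logits, concat
from .nn import autograd as ag

__all__ = [
    "BoundingBox", "BoxPair", "PiouParams",
    "iou", "penalty_P", "f", "piou", "l_piou", "attention_u", "l_piou_v2",
    "ciou_loss_pair", "piou_loss", "piou_v2_loss", "ciou_loss", "LossBreakdown",
    "DetectionLoss",
]


@dataclass(frozen=True)
class BoundingBox:
    """Class-labelled axis-aligned box, absolute xyxy pixels, origin top-left."""

    class_id: int
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self):
        return self.x2 - self.x1

    @property
    def height(self):
        return self.y2 - self.y1

    @property
    def area(self):
        return self.width * self.height

    def as_array(self):
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)


@dataclass(frozen=True)
class BoxPair:
    pred: BoundingBox
    target: BoundingBox


@dataclass(frozen=True)
class PiouParams:
    lambda_: float = 1.1
    detach_attention: bool = True

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")


# ---------------------------------------------------------------------------
# scalar reference implementations
# ---------------------------------------------------------------------------

def iou(pair: BoxPair) -> float:
    """Intersection area over union area."""
    p, t = pair.pred, pair.target
    iw = min(p.x2, t.x2) - max(p.x1, t.x1)
    ih = min(p.y2, t.y2) - max(p.y1, t.y1)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = p.area + t.area - inter
    return inter / union


def penalty_P(pair: BoxPair) -> float:
    """Mean target-normalised distance between corresponding box edges."""
    p, t = pair.pred, pair.target
    return (
        abs(p.x1 - t.x1) / t.width
        + abs(p.x2 - t.x2) / t.width
        + abs(p.y1 - t.y1) / t.height
        + abs(p.y2 - t.y2) / t.height
    ) / 4.0


def f(x: float) -> float:
    """Penalty transform 1 - exp(-x^2); even, increasing on x >= 0."""
    return 1.0 - math.exp(-(x * x))


def piou(pair: BoxPair) -> float:
    return iou(pair) - f(penalty_P(pair))


def l_piou(pair: BoxPair) -> float:
    return 1.0 - piou(pair)


def attention_u(x: float) -> float:
    """Attention weight u(x) = 3x * exp(-x^2)."""
    return 3.0 * x * math.exp(-(x * x))


def l_piou_v2(pair: BoxPair, params: PiouParams = PiouParams()) -> float:
    q = math.exp(-penalty_P(pair))
    return attention_u(params.lambda_ * q) * l_piou(pair)


def ciou_loss_pair(pair: BoxPair) -> float:
    """Scalar CIoU loss (baseline arm), standard published form."""
    p, t = pair.pred, pair.target
    pa, ta = p.as_array(), t.as_array()
    return float(ciou_loss(Tensor(pa[None]), ta[None]).data[0])


# ---------------------------------------------------------------------------
# batched autograd versions (pred differentiable, target fixed)
# ---------------------------------------------------------------------------

def _pairwise_iou_t(pred: Tensor, target: np.ndarray):
    tgt = np.asarray(target, dtype=pred.dtype)
    x1 = ag.maximum(pred[:, 0], tgt[:, 0])
    y1 = ag.maximum(pred[:, 1], tgt[:, 1])
    x2 = ag.minimum(pred[:, 2], tgt[:, 2])
    y2 = ag.minimum(pred[:, 3], tgt[:, 3])
    iw = (x2 - x1).clamp(lo=0.0)
    ih = (y2 - y1).clamp(lo=0.0)
    inter = iw * ih
    area_p = (pred[:, 2] - pred[:, 0]) * (pred[:, 3] - pred[:, 1])
    area_t = (tgt[:, 2] - tgt[:, 0]) * (tgt[:, 3] - tgt[:, 1])
    union = area_p + Tensor(area_t) - inter
    return inter / (union + 1e-9), tgt


def _piou_core(pred: Tensor, target: np.ndarray):
    """Shared pieces: (L_PIoU tensor, penalty tensor)."""
    iou_t, tgt = _pairwise_iou_t(pred, target)
    tw = tgt[:, 2] - tgt[:, 0]
    th = tgt[:, 3] - tgt[:, 1]
    p_t = ((pred[:, 0] - tgt[:, 0]).abs() / Tensor(tw)
           + (pred[:, 2] - tgt[:, 2]).abs() / Tensor(tw)
           + (pred[:, 1] - tgt[:, 1]).abs() / Tensor(th)
           + (pred[:, 3] - tgt[:, 3]).abs() / Tensor(th)) * 0.25
    f_t = 1.0 - (-(p_t * p_t)).exp()
    return (1.0 - iou_t) + f_t, p_t


def piou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise L_PIoU = (1 - IoU) + f(P) for matched (M,4) xyxy boxes."""
    loss, _ = _piou_core(pred, target)
    return loss


def piou_v2_loss(pred: Tensor, target: np.ndarray,
                 params: PiouParams = PiouParams()) -> Tensor:
    """Elementwise PIoU-v2 loss for matched (M,4) xyxy boxes.

    The attention factor u(lambda*q) is treated as a detached weight by
    default (configurable) — gradients flow through IoU and f(P) only.
    """
    loss, p_t = _piou_core(pred, target)
    lam_q = params.lambda_ * (-p_t).exp()
    if params.detach_attention:
        lq = lam_q.data
        atten = Tensor(3.0 * lq * np.exp(-lq * lq))
    else:
        atten = 3.0 * lam_q * (-(lam_q * lam_q)).exp()
    return atten * loss


def ciou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise CIoU loss for matched (M,4) xyxy boxes."""
    iou_t, tgt = _pairwise_iou_t(pred, target)
    # enclosing box diagonal
    ex1 = ag.minimum(pred[:, 0], tgt[:, 0])
    ey1 = ag.minimum(pred[:, 1], tgt[:, 1])
    ex2 = ag.maximum(pred[:, 2], tgt[:, 2])
    ey2 = ag.maximum(pred[:, 3], tgt[:, 3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + 1e-9
    # centre distance
    dx = (pred[:, 0] + pred[:, 2] - tgt[:, 0] - tgt[:, 2]) * 0.5
    dy = (pred[:, 1] + pred[:, 3] - tgt[:, 1] - tgt[:, 3]) * 0.5
    rho2 = dx * dx + dy * dy
    # aspect-ratio consistency
    w_p = pred[:, 2] - pred[:, 0]
    h_p = (pred[:, 3] - pred[:, 1]) + 1e-9
    w_t = tgt[:, 2] - tgt[:, 0]
    h_t = tgt[:, 3] - tgt[:, 1]
    atan_t = np.arctan(w_t / (h_t + 1e-9))
    v = (4.0 / math.pi**2) * (Tensor(atan_t) - _atan(w_p / h_p)) ** 2
    with ag.no_grad():
        alpha = v.data / (1.0 - iou_t.data + v.data + 1e-9)
    return 1.0 - iou_t + rho2 / c2 + Tensor(alpha) * v


def _atan(x: Tensor) -> Tensor:
    out = np.arctan(x.data)

    def backward(grad, a=x):
        ag._accum(a, grad / (1.0 + a.data * a.data))

    return Tensor._make(out, (x,), backward)


def sample_box_pairs(n: int, rng=None, span: float = 100.0):
    """Vectorised sampler of n random valid (pred, target) box pairs.

    Positions are uniform over the span and sizes over (0.5, span/2], which
    yields a mix of disjoint, overlapping and nested configurations.
    Returns (pred, target) arrays of shape (n, 4), xyxy.
    """
    rng = rng or np.random.default_rng()

    def boxes():
        xy = rng.uniform(0, span, (n, 2))
        wh = rng.uniform(0.5, span / 2, (n, 2))
        return np.concatenate([xy, xy + wh], axis=1)

    return boxes(), boxes()


# ---------------------------------------------------------------------------
# composite detection loss
# ---------------------------------------------------------------------------

@dataclass
class LossBreakdown:
    box: float
    cls: float
    dfl: float
    weights: tuple = (7.5, 0.5, 1.5)

    @property
    def total(self) -> float:
        wb, wc, wd = self.weights
        return wb * self.box + wc * self.cls + wd * self.dfl


class DetectionLoss:
    """YOLOv8-style composite loss with a pluggable box-IoU term.

    box_loss: 'piouv2' or 'ciou'.  Weights follow the baseline trainer.
    """

    def __init__(self, num_classes=2, reg_bins=16, box_loss="piouv2",
                 piou_params: PiouParams = PiouParams(),
                 weights=(7.5, 0.5, 1.5)):
        from .assigner import TaskAlignedAssigner

        if box_loss not in ("piouv2", "ciou"):
            raise ValueError(f"unknown box loss {box_loss!r}")
        self.num_classes = num_classes
        self.reg_bins = reg_bins
        self.box_loss = box_loss
        self.piou_params = piou_params
        self.weights = weights
        self.assigner = TaskAlignedAssigner(num_classes=num_classes)

    def __call__(self, raw, gt_boxes, gt_labels):
        """raw: RawPrediction; gt_boxes: list of (K_i,4); gt_labels: list of (K_i,).

        Returns (total_loss Tensor, LossBreakdown).
        """
        from .head import anchor_points

        nc, bins = self.num_classes, self.reg_bins
        shapes = [c.shape[2:] for c in raw.cls]
        pts, strs = anchor_points(shapes, raw.strides)
        n = raw.cls[0].shape[0]

        cls_t = concat(
            [c.reshape(n, nc, -1).transpose(0, 2, 1) for c in raw.cls], axis=1)
        reg_t = concat(
            [r.reshape(n, 4 * bins, -1).transpose(0, 2, 1) for r in raw.reg], axis=1)

        # differentiable decode: bin softmax -> expected distances -> boxes
        a = cls_t.shape[1]
        reg4 = reg_t.reshape(n, a, 4, bins)
        prob = ag.softmax(reg4, axis=-1)
        proj = np.arange(bins, dtype=np.float32).reshape(bins, 1)
        dist = prob.reshape(n * a * 4, bins).matmul(Tensor(proj)).reshape(n, a, 4)
        pts_f = pts.astype(np.float32)
        strs_f = strs.astype(np.float32)[None, :, None]
        x1y1 = Tensor(pts_f[None]) - dist[:, :, :2] * strs_f
        x2y2 = Tensor(pts_f[None]) + dist[:, :, 2:] * strs_f
        boxes_t = concat([x1y1, x2y2], axis=2)

        with ag.no_grad():
            scores_np = 1.0 / (1.0 + np.exp(-cls_t.data))
            assign = self.assigner(
                scores_np, boxes_t.data, pts, strs, gt_boxes, gt_labels)

        target_scores = assign.target_scores            # (N, A, nc)
        fg = assign.fg_mask                             # (N, A) bool
        score_sum = max(float(target_scores.sum()), 1.0)

        cls_loss = bce_with_logits(cls_t, target_scores).sum() / score_sum

        if fg.any():
            pred_boxes_fg = boxes_t[fg]                  # (M, 4)
            tgt_boxes_fg = assign.target_boxes[fg]       # (M, 4) numpy
            w = target_scores.sum(-1)[fg].astype(np.float32)  # alignment weights
            if self.box_loss == "piouv2":
                per_box = piou_v2_loss(pred_boxes_fg, tgt_boxes_fg, self.piou_params)
            else:
                per_box = ciou_loss(pred_boxes_fg, tgt_boxes_fg)
            box_loss = (per_box * Tensor(w)).sum() / score_sum

            # distribution-focal term on the same matches
            tgt_dist = self._target_distances(tgt_boxes_fg, pts[None], strs, fg)
            dist_logits = reg4[fg].reshape(-1, bins)     # (M*4, bins)
            dfl = self._dfl(dist_logits, tgt_dist.reshape(-1))
            dfl_loss = (dfl.reshape(-1, 4).mean(axis=1) * Tensor(w)).sum() / score_sum
        else:
            box_loss = Tensor(np.float32(0.0))
            dfl_loss = Tensor(np.float32(0.0))

        wb, wc, wd = self.weights
        total = box_loss * wb + cls_loss * wc + dfl_loss * wd
        breakdown = LossBreakdown(
            box=float(box_loss.data), cls=float(cls_loss.data),
            dfl=float(dfl_loss.data), weights=self.weights)
        return total, breakdown

    def _target_distances(self, tgt_boxes, pts, strs, fg):
        """ltrb distances of targets from anchor points, in stride units."""
        pts_fg = np.broadcast_to(pts, (fg.shape[0], pts.shape[1], 2))[fg]
        strs_fg = np.broadcast_to(strs[None], fg.shape)[fg][:, None]
        lt = (pts_fg - tgt_boxes[:, :2]) / strs_fg
        rb = (tgt_boxes[:, 2:] - pts_fg) / strs_fg
        d = np.concatenate([lt, rb], axis=1)
        return np.clip(d, 0, self.reg_bins - 1 - 0.01)

    def _dfl(self, logits: Tensor, target: np.ndarray) -> Tensor:
        """Cross-entropy against the two bins bracketing each target."""
        tl = np.floor(target).astype(int)
        tr = tl + 1
        wl = tr - target
        wr = 1.0 - wl
        logp = _log_softmax(logits)
        idx = np.arange(len(target))
        nll_l = -logp[idx, tl]
        nll_r = -logp[idx, np.minimum(tr, self.reg_bins - 1)]
        return nll_l * Tensor(wl.astype(np.float32)) + nll_r * Tensor(wr.astype(np.float32))


def _log_softmax(x: Tensor) -> Tensor:
    m = x.data.max(axis=-1, keepdims=True)
    shifted = x - Tensor(m)
    return shifted - shifted.exp().sum(axis=-1, keepdims=True).log()
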