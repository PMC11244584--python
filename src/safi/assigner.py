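"""Task-aligned assignment of anchors to ground-truth boxes (numpy).

Candidate anchors are those whose centre lies inside a ground-truth box;
each target keeps its top-k candidates by the alignment metric
score^alpha * IoU^beta; anchors claimed by several targets go to the one
with the highest IoU.  Target classification scores are the normalised
alignment metrics (soft labels), as in the baseline trainer.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head import box_iou_matrix

__all__ = ["AssignResult", "TaskAlignedAssigner"]


@dataclass
class AssignResult:
    fg_mask: np.ndarray        # (N, A) bool
    target_boxes: np.ndarray   # (N, A, 4)
    target_scores: np.ndarray  # (N, A, nc)


class TaskAlignedAssigner:
    def __init__(self, num_classes=2, topk=10, alpha=0.5, beta=6.0, eps=1e-9):
        self.num_classes = num_classes
        self.topk = topk
        self.alpha = alpha
        self.beta = beta
        self.eps = eps

    def __call__(self, scores, pred_boxes, pts, strs, gt_boxes, gt_labels):
        """scores: (N, A, nc) sigmoid scores; pred_boxes: (N, A, 4);
        pts: (A, 2) anchor centres; gt_boxes: list of (K_i, 4);
        gt_labels: list of (K_i,) ints."""
        n, a, nc = scores.shape
        fg = np.zeros((n, a), dtype=bool)
        tboxes = np.zeros((n, a, 4))
        tscores = np.zeros((n, a, nc), dtype=np.float32)

        for i in range(n):
            gtb = np.asarray(gt_boxes[i], dtype=float).reshape(-1, 4)
            gtl = np.asarray(gt_labels[i], dtype=int).reshape(-1)
            k = len(gtb)
            if k == 0:
                continue
            inside = (
                (pts[:, 0] > gtb[:, None, 0]) & (pts[:, 0] < gtb[:, None, 2])
                & (pts[:, 1] > gtb[:, None, 1]) & (pts[:, 1] < gtb[:, None, 3])
            )  # (K, A)
            ious = box_iou_matrix(gtb, pred_boxes[i])          # (K, A)
            cls_score = scores[i][:, gtl].T                    # (K, A)
            metric = (cls_score ** self.alpha) * (ious ** self.beta)
            metric = np.where(inside, metric, 0.0)

            # top-k candidates per target
            mask = np.zeros_like(inside)
            kk = min(self.topk, a)
            top = np.argpartition(-metric, kk - 1, axis=1)[:, :kk]
            rows = np.repeat(np.arange(k), kk)
            cand = np.zeros_like(inside)
            cand[rows, top.ravel()] = True
            mask = cand & inside & (metric > 0)

            # resolve anchors claimed by multiple targets: keep highest IoU
            claimed = mask.sum(axis=0) > 1
            if claimed.any():
                best_gt = np.argmax(np.where(mask, ious, -1.0), axis=0)
                resolved = np.zeros_like(mask)
                cols = np.where(mask.any(axis=0))[0]
                resolved[best_gt[cols], cols] = True
                mask = resolved

            assigned_gt = np.argmax(mask, axis=0)
            anchor_fg = mask.any(axis=0)
            fg[i] = anchor_fg
            tboxes[i, anchor_fg] = gtb[assigned_gt[anchor_fg]]

            # normalised soft labels: metric / max_metric * max_iou per target
            norm = np.zeros((k, a), dtype=np.float32)
            for g in range(k):
                mg = metric[g] * mask[g]
                mmax = mg.max()
                if mmax > self.eps:
                    imax = np.where(mask[g], ious[g], 0.0).max()
                    norm[g] = mg / (mmax + self.eps) * imax
            soft = norm.max(axis=0)
            lab = gtl[assigned_gt]
            tscores[i, np.arange(a), lab] = np.where(anchor_fg, soft, 0.0)
        return AssignResult(fg_mask=fg, target_boxes=tboxes, target_scores=tscores)
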