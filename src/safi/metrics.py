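"""Detection metrics: precision, recall, per-class AP and mAP@0.5.

Matching is greedy in descending score with at most one detection per
ground-truth box; AP integrates the all-point precision envelope.  Ties in
score are broken deterministically by box area, then lexicographically by
coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .head import box_iou_matrix

__all__ = ["EvalResult", "detection_metrics", "average_precision"]


@dataclass
class EvalResult:
    precision: float
    recall: float
    map50: float
    per_class_ap: dict
    pr_curves: dict = field(default_factory=dict)  # class -> (recall, precision)

    def as_dict(self):
        return {
            "precision": self.precision, "recall": self.recall,
            "map50": self.map50,
            "per_class_ap": dict(self.per_class_ap),
        }


def _sort_detections(dets):
    """dets: list of (img_id, class, score, x1, y1, x2, y2) -> sorted indices."""
    if not dets:
        return []
    arr = np.array([[d[2], (d[5] - d[3]) * (d[6] - d[4]), d[3], d[4], d[5], d[6]]
                    for d in dets])
    return np.lexsort((arr[:, 5], arr[:, 4], arr[:, 3], arr[:, 2],
                       -arr[:, 1], -arr[:, 0]))


def _match_class(dets, gts, iou_thresh):
    """Greedy matching for one class.

    dets: list of (img_id, score, box); gts: dict img_id -> (K,4) array.
    Returns tp/fp flags aligned with score-sorted detections and n_gt.
    """
    order = _sort_detections([(d[0], None, d[1], *d[2]) for d in dets])
    used = {img: np.zeros(len(b), dtype=bool) for img, b in gts.items()}
    n_gt = sum(len(b) for b in gts.values())
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    scores = np.zeros(len(dets))
    for rank, di in enumerate(order):
        img, score, box = dets[di]
        scores[rank] = score
        gt = gts.get(img)
        if gt is None or len(gt) == 0:
            fp[rank] = 1
            continue
        ious = box_iou_matrix(np.asarray(box)[None], gt)[0]
        ious[used[img]] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= iou_thresh:
            tp[rank] = 1
            used[img][j] = True
        else:
            fp[rank] = 1
    return tp, fp, scores, n_gt


def average_precision(tp, fp, n_gt):
    """All-point interpolation over the precision envelope."""
    if n_gt == 0:
        return 0.0, np.array([0.0]), np.array([0.0])
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    return ap, mrec, mpre


def detection_metrics(predictions, ground_truths, conf_thresh=0.25,
                      iou_thresh=0.5, num_classes=2) -> EvalResult:
    """predictions: per-image lists of (class, score, x1, y1, x2, y2);
    ground_truths: per-image lists of BoundingBox (or (cls, x1, y1, x2, y2))."""
    gt_by_class = {c: {} for c in range(num_classes)}
    total_gt = 0
    for img_id, boxes in enumerate(ground_truths):
        for b in boxes:
            if hasattr(b, "class_id"):
                c, arr = b.class_id, b.as_array()
            else:
                c, arr = int(b[0]), np.asarray(b[1:], dtype=float)
            gt_by_class[c].setdefault(img_id, []).append(arr)
            total_gt += 1
    for c in gt_by_class:
        gt_by_class[c] = {k: np.stack(v) for k, v in gt_by_class[c].items()}

    if total_gt == 0:
        warnings.warn("no ground-truth boxes: metrics defined as 0")
        return EvalResult(0.0, 0.0, 0.0, {c: 0.0 for c in range(num_classes)})

    per_class_ap, pr_curves = {}, {}
    micro_tp = micro_fp = 0
    for c in range(num_classes):
        dets = []
        for img_id, preds in enumerate(predictions):
            for p in preds:
                if int(p[0]) == c:
                    dets.append((img_id, float(p[1]), np.asarray(p[2:6], dtype=float)))
        tp, fp, scores, n_gt = _match_class(dets, gt_by_class[c], iou_thresh)
        if n_gt == 0:
            continue
        ap, mrec, mpre = average_precision(tp, fp, n_gt)
        per_class_ap[c] = ap
        pr_curves[c] = (mrec, mpre)
        keep = scores >= conf_thresh
        micro_tp += int(tp[keep].sum())
        micro_fp += int(fp[keep].sum())

    map50 = float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0
    precision = micro_tp / max(micro_tp + micro_fp, 1)
    recall = micro_tp / total_gt
    return EvalResult(float(precision), float(recall), map50, per_class_ap, pr_curves)
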