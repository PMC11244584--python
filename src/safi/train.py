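"""Training loop and evaluation driver.

Hyperparameter defaults mirror the source training strategy (300 epochs,
SGD, lr0 0.01, momentum 0.937, weight decay 0.0005, batch 16), with a
3-epoch warmup, linear decay, optional mosaic augmentation, and automatic
termination once validation mAP@0.5 stops improving.
"""
from __future__ import annotations

import csv
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .assembly import DetectionModel
from .data import mosaic as mosaic_op
from .head import decode_predictions
from .losses import BoundingBox
from .metrics import EvalResult, detection_metrics

__all__ = ["TrainConfig", "Sample", "train", "evaluate", "measure_fps"]


@dataclass
class TrainConfig:
    epochs: int = 300
    lr0: float = 0.01
    optimizer: str = "SGD"
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch: int = 16
    workers: int = 8          # kept for config parity; loading is in-process
    input_size: int = 640
    seed: int = 0
    mosaic_enabled: bool = True
    warmup_epochs: int = 3
    lr_final_frac: float = 0.01
    patience: int = 50        # epochs of no val-mAP improvement before stop
    eval_interval: int = 10
    conf_thresh: float = 0.25
    iou_thresh: float = 0.5
    nms_iou: float = 0.7

    def __post_init__(self):
        if self.optimizer != "SGD":
            raise ValueError("only SGD is supported")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


@dataclass
class Sample:
    image: np.ndarray            # uint8 HxWx3
    boxes: list                  # list of BoundingBox


def _resize_sample(sample: Sample, size: int) -> Sample:
    h, w = sample.image.shape[:2]
    if (h, w) == (size, size):
        return sample
    img = np.asarray(Image.fromarray(sample.image).resize((size, size), Image.BILINEAR))
    sx, sy = size / w, size / h
    boxes = [BoundingBox(b.class_id, b.x1 * sx, b.y1 * sy, b.x2 * sx, b.y2 * sy)
             for b in sample.boxes]
    return Sample(img, boxes)


def _to_batch(samples):
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = imgs.transpose(0, 3, 1, 2)
    gt_boxes = [np.array([b.as_array() for b in s.boxes]).reshape(-1, 4)
                for s in samples]
    gt_labels = [np.array([b.class_id for b in s.boxes], dtype=int)
                 for s in samples]
    return nn.Tensor(x), gt_boxes, gt_labels


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    if epoch < cfg.warmup_epochs:
        return cfg.lr0 * (0.1 + 0.9 * (epoch + 1) / cfg.warmup_epochs)
    t = (epoch - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs, 1)
    return cfg.lr0 * ((1.0 - t) + t * cfg.lr_final_frac)


def train(model: DetectionModel, dataset, cfg: TrainConfig,
          val_dataset=None, out_dir=None, log_fn=None):
    """Train ``model`` on a list of Samples; returns (history, best_state).

    history: list of per-epoch dicts (losses, lr, optional val metrics).
    The best-by-mAP state dict is retained (and written to ``out_dir`` as
    an .npz checkpoint when given).  Raises RuntimeError on divergence.
    """
    rng = np.random.default_rng(cfg.seed)
    dataset = [_resize_sample(s, cfg.input_size) for s in dataset]
    val_dataset = val_dataset or dataset
    loss_fn = model.make_loss()
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    history = []
    best = {"map50": -1.0, "state": None, "epoch": -1}
    epochs_since_best = 0
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(cfg, epoch)
        order = rng.permutation(len(dataset))
        model.train()
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch):
            idx = order[start : start + cfg.batch]
            samples = [dataset[i] for i in idx]
            if cfg.mosaic_enabled and len(dataset) >= 4 and rng.random() < 0.5:
                pick = rng.choice(len(dataset), size=4, replace=False)
                img, boxes = mosaic_op(
                    [dataset[i].image for i in pick],
                    [dataset[i].boxes for i in pick],
                    cfg.input_size, seed=int(rng.integers(2**31 - 1)))
                samples = samples[:-1] + [Sample(img, boxes)]
            x, gtb, gtl = _to_batch(samples)
            raw = model(x)
            total, parts = loss_fn(raw, gtb, gtl)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: {parts}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in (("box", parts.box), ("cls", parts.cls),
                         ("dfl", parts.dfl), ("total", float(total.data))):
                sums[k] += v
            n_batches += 1
        rec = {f"loss_{k}": v / max(n_batches, 1) for k, v in sums.items()}
        rec.update(epoch=epoch, lr=opt.lr)

        if (epoch + 1) % cfg.eval_interval == 0 or epoch == cfg.epochs - 1:
            res = evaluate(model, val_dataset, conf_thresh=cfg.conf_thresh,
                           iou_thresh=cfg.iou_thresh, nms_iou=cfg.nms_iou,
                           input_size=cfg.input_size)
            rec.update(val_precision=res.precision, val_recall=res.recall,
                       val_map50=res.map50)
            if res.map50 > best["map50"] + 1e-6:
                best = {"map50": res.map50, "state": model.state_dict(),
                        "epoch": epoch}
                epochs_since_best = 0
            else:
                epochs_since_best += cfg.eval_interval
            if best["map50"] >= 0.995 or epochs_since_best >= cfg.patience:
                history.append(rec)
                if log_fn:
                    log_fn(rec)
                break
        history.append(rec)
        if log_fn:
            log_fn(rec)

    if best["state"] is None:
        best = {"map50": float("nan"), "state": model.state_dict(),
                "epoch": cfg.epochs - 1}
    if out_dir:
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            keys = sorted({k for r in history for k in r})
            wr = csv.DictWriter(fh, fieldnames=keys)
            wr.writeheader()
            wr.writerows(history)
        np.savez(out_dir / "best.npz", **best["state"])
    return history, best


def predict(model: DetectionModel, images, conf_thresh=0.25, nms_iou=0.7,
            input_size=None, batch=8):
    """Run inference on uint8 HxWx3 images; per-image detection lists in
    original pixel coordinates."""
    model.eval()
    results = []
    size = input_size or model.cfg.input_size
    for start in range(0, len(images), batch):
        chunk = images[start : start + batch]
        scales = []
        arrs = []
        for img in chunk:
            h, w = img.shape[:2]
            if (h, w) != (size, size):
                img = np.asarray(Image.fromarray(img).resize((size, size),
                                                             Image.BILINEAR))
            scales.append((w / size, h / size))
            arrs.append(img)
        x = nn.Tensor(np.stack(arrs).astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
        with nn.no_grad():
            raw = model(x)
        dets = decode_predictions(raw, conf_thresh, nms_iou,
                                  image_size=(size, size))
        for (sx, sy), d in zip(scales, dets):
            results.append([(c, s, x1 * sx, y1 * sy, x2 * sx, y2 * sy)
                            for c, s, x1, y1, x2, y2 in d])
    return results


def evaluate(model: DetectionModel, dataset, conf_thresh=0.25, iou_thresh=0.5,
             nms_iou=0.7, input_size=None, decode_conf=0.001) -> EvalResult:
    """mAP@0.5 / precision / recall on a list of Samples.

    Detections are decoded at a low confidence floor so the full PR curve is
    integrated; precision and recall are reported at ``conf_thresh``.
    """
    preds = predict(model, [s.image for s in dataset],
                    conf_thresh=decode_conf, nms_iou=nms_iou,
                    input_size=input_size)
    gts = [s.boxes for s in dataset]
    return detection_metrics(preds, gts, conf_thresh=conf_thresh,
                             iou_thresh=iou_thresh,
                             num_classes=model.cfg.num_classes)


def measure_fps(model: DetectionModel, input_size=640, n_iters=10):
    """Wall-clock forward throughput (hardware-dependent; not a metric that
    is ever asserted).  Returns (fps, batch1_latency_seconds)."""
    model.eval()
    x = nn.Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    with nn.no_grad():
        model(x)  # warmup
        t0 = time.perf_counter()
        for _ in range(n_iters):
            model(x)
        dt = time.perf_counter() - t0
    latency = dt / n_iters
    return 1.0 / latency, latency
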