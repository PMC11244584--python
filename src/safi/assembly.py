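"""Model assembly, ablation variants, and parameter/FLOP accounting.

The four structural/loss toggles (backbone, neck convolution, head, box
loss) form a 16-variant ablation grid.  Widths and depths are calibrated
repository constants; the neck's fused widths depend on the backbone's tap
widths (the star backbone feeds a slimmer top-down path), which is why the
printed budgets of combined variants are not simple sums of the single-swap
deltas.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import nn
from .backbone import (STAR_BACKBONE_CONFIG, BackboneConfig, DarknetBackbone,
                       StarNetBackbone)
from .head import DetectELHead, DetectHead, HeadSpec, RawPrediction
from .losses import DetectionLoss, PiouParams
from .neck import PanNeck
from .nn import Tensor

__all__ = [
    "DetectionModelConfig", "ModelSummary", "DetectionModel",
    "build_model", "count_parameters", "count_flops", "model_summary",
    "ablation_table", "variant_config", "load_model_config",
    "DARKNET_NECK_WIDTHS", "STAR_NECK_WIDTHS",
]

BACKBONES = ("darknet", "starnet")
NECKS = ("c2f", "c2f_elc")
HEADS = ("detect", "detect_el")
LOSSES = ("ciou", "piouv2")

# Calibrated fused-width constants (see configs/*.yaml).
DARKNET_NECK_WIDTHS = (64, 128, 256)
STAR_NECK_WIDTHS = (64, 112, 224)


@dataclass(frozen=True)
class DetectionModelConfig:
    backbone: str = "darknet"
    neck: str = "c2f"
    head: str = "detect"
    loss: str = "ciou"
    num_classes: int = 2
    input_size: int = 640
    piou_lambda: float = 1.1
    backbone_config: BackboneConfig = field(default_factory=BackboneConfig)

    def __post_init__(self):
        for val, allowed, name in ((self.backbone, BACKBONES, "backbone"),
                                   (self.neck, NECKS, "neck"),
                                   (self.head, HEADS, "head"),
                                   (self.loss, LOSSES, "loss")):
            if val not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {val!r}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    @property
    def neck_widths(self):
        return STAR_NECK_WIDTHS if self.backbone == "starnet" else DARKNET_NECK_WIDTHS


def variant_config(starnet=False, elc=False, detect_el=False, piouv2=False,
                   **kwargs) -> DetectionModelConfig:
    return DetectionModelConfig(
        backbone="starnet" if starnet else "darknet",
        neck="c2f_elc" if elc else "c2f",
        head="detect_el" if detect_el else "detect",
        loss="piouv2" if piouv2 else "ciou",
        **kwargs,
    )


YOLO_SAFI = variant_config(starnet=True, elc=True, detect_el=True, piouv2=True)
BASELINE = variant_config()


class DetectionModel(nn.Module):
    def __init__(self, cfg: DetectionModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        if cfg.backbone == "starnet":
            self.backbone = StarNetBackbone(cfg.backbone_config, rng=rng)
        else:
            self.backbone = DarknetBackbone(rng=rng)
        taps = self.backbone.out_channels
        widths = cfg.neck_widths
        self.neck = PanNeck(taps, widths, use_elc=(cfg.neck == "c2f_elc"), rng=rng)
        spec = HeadSpec(num_classes=cfg.num_classes, in_channels=widths)
        if cfg.head == "detect_el":
            self.head = DetectELHead(spec, rng=rng)
        else:
            self.head = DetectHead(spec, rng=rng)

    def forward(self, x) -> RawPrediction:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        return self.head(self.neck(self.backbone(x)))

    def make_loss(self) -> DetectionLoss:
        return DetectionLoss(
            num_classes=self.cfg.num_classes,
            box_loss=self.cfg.loss,
            piou_params=PiouParams(lambda_=self.cfg.piou_lambda),
        )


def build_model(cfg: DetectionModelConfig, seed: int = 0) -> DetectionModel:
    return DetectionModel(cfg, rng=np.random.default_rng(seed))


def count_parameters(model: nn.Module, trainable_only: bool = True) -> int:
    """Exact count of trainable scalars."""
    if trainable_only:
        return sum(p.size for p in model.parameters() if p.requires_grad)
    return model.num_parameters()


def count_flops(model: DetectionModel, input_size: int | None = None) -> int:
    """FLOPs of one forward pass at ``input_size`` (2 x conv MACs)."""
    size = input_size or model.cfg.input_size
    if size % 32:
        raise ValueError("input_size must be divisible by 32")
    x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    was_training = model.training
    model.eval()
    with nn.no_grad(), nn.count_macs() as tally:
        model(x)
    model.train(was_training)
    return tally.flops


@dataclass
class ModelSummary:
    parameters: int
    flops: int
    input_size: int
    per_module: dict

    @property
    def parameters_m(self) -> float:
        return round(self.parameters / 1e6, 1)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 1)

    def as_dict(self):
        return {
            "parameters": self.parameters,
            "parameters_M": self.parameters_m,
            "flops": self.flops,
            "flops_G": self.flops_g,
            "input_size": self.input_size,
            "per_module": self.per_module,
        }


def model_summary(model: DetectionModel, input_size: int | None = None) -> ModelSummary:
    per = {name: count_parameters(getattr(model, name))
           for name in ("backbone", "neck", "head")}
    total = count_parameters(model)
    assert total == sum(per.values()), "per-module breakdown must sum to total"
    return ModelSummary(
        parameters=total,
        flops=count_flops(model, input_size),
        input_size=input_size or model.cfg.input_size,
        per_module=per,
    )


def ablation_table(configs=None, input_size=640, num_classes=2):
    """Parameter/FLOP rows for a list of configs (default: full 16-way grid).

    Accuracy columns are left blank: the originating detection dataset is
    not public.  Structural duplicates (loss toggles) share measurements.
    """
    if configs is None:
        configs = [
            variant_config(*combo, num_classes=num_classes)
            for combo in itertools.product((False, True), repeat=4)
        ]
    rows = []
    cache = {}
    for cfg in configs:
        key = (cfg.backbone, cfg.neck, cfg.head, cfg.num_classes)
        if key not in cache:
            model = build_model(cfg, seed=0)
            p = count_parameters(model)
            f_ = count_flops(model, input_size)
            cache[key] = (p, f_)
        p, f_ = cache[key]
        rows.append({
            "backbone": cfg.backbone, "neck": cfg.neck, "head": cfg.head,
            "loss": cfg.loss,
            "parameters": p, "parameters_M": round(p / 1e6, 1),
            "flops": f_, "flops_G": round(f_ / 1e9, 1),
            "precision": "", "recall": "", "map50": "",
        })
    return rows


def load_model_config(path) -> DetectionModelConfig:
    """Read a model-config YAML (see configs/ for the shipped examples)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    bb = raw.get("backbone", {})
    kwargs = {}
    if isinstance(bb, dict):
        kwargs["backbone"] = bb.get("type", "darknet")
        bc_fields = {k: v for k, v in bb.items() if k != "type"}
        if bc_fields:
            if "stage_channels" in bc_fields:
                bc_fields["stage_channels"] = tuple(bc_fields["stage_channels"])
            if "stage_depths" in bc_fields:
                bc_fields["stage_depths"] = tuple(bc_fields["stage_depths"])
            kwargs["backbone_config"] = replace(BackboneConfig(), **bc_fields)
    else:
        kwargs["backbone"] = bb
    neck = raw.get("neck", {})
    kwargs["neck"] = neck.get("type", "c2f") if isinstance(neck, dict) else neck
    head = raw.get("head", {})
    kwargs["head"] = head.get("type", "detect") if isinstance(head, dict) else head
    loss = raw.get("loss", {})
    if isinstance(loss, dict):
        kwargs["loss"] = loss.get("box", "ciou")
        if "lambda" in loss:
            kwargs["piou_lambda"] = float(loss["lambda"])
    else:
        kwargs["loss"] = loss
    for key in ("num_classes", "input_size"):
        if key in raw:
            kwargs[key] = int(raw[key])
    return DetectionModelConfig(**kwargs)
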