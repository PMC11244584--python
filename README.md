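# safi

A lightweight two-class flower-filament detector, implemented from scratch in
scientific Python (numpy + a small built-in autograd engine — no deep-learning
framework required).

The detector family is a single-stage anchor-free architecture with four
independent toggles, forming a 16-variant ablation grid:

| component | stock | lightweight swap |
|---|---|---|
| backbone | DarkNet-style C2f (`darknet`) | star-operation blocks (`starnet`) |
| neck conv | C2f bottlenecks (`c2f`) | grouped multi-kernel "ELC" conv (`c2f_elc`) |
| head | per-level towers (`detect`) | shared conv tower + GroupNorm + per-level Scale (`detect_el`) |
| box loss | CIoU (`ciou`) | PIoUv2 (`piouv2`) |

With `num_classes=2` at 640x640 the baseline builds at 3.0 M parameters /
8.1 GFLOPs and the full lightweight variant at 1.5 M / 4.8 GFLOPs (50.0% and
40.7% reductions); the single-swap ablations land at 2.2 M (backbone), 2.9 M
(neck) and 2.3 M (head).

Because the original field dataset is not public, the package ships a seeded
synthetic scene generator (textured background, small elliptical two-class
targets, lighting jitter, partial occlusion with a per-object occlusion
fraction; objects occluded >70% are drawn but unlabelled) plus VOC-XML/YOLO-txt
label I/O, the 7:2:1 split, photometric/rotation/noise augmentation and mosaic
composition.

## CLI

```bash
safi generate --n 200 --out data/ --seed 7        # synthetic dataset + 7:2:1 split
safi summary --variant yolo-safi --imgsz 640      # parameter / FLOP summary (JSON)
safi summary --config configs/yolo_safi.yaml
safi ablate --grid full --out ablation.csv        # 16-variant budget table
safi train --n-synthetic 16 --epochs 30 --imgsz 320 --seed 0 --out runs/train
safi val   --n-synthetic 8 --imgsz 320            # precision / recall / mAP@0.5
safi detect image.png --weights runs/train/best.npz --conf 0.25
```

Config precedence: CLI flag > YAML (`--config`) > built-in defaults. Every
subcommand honours `--seed` and writes a `manifest.json` before computing.

## Layout

```
src/safi/nn/        numpy autograd engine (conv2d, norms, pooling, SGD, FLOP tally)
src/safi/star.py    scalar star operation and its coefficient expansion
src/safi/backbone.py  star-block and DarkNet backbones (stride-8/16/32 pyramid)
src/safi/neck.py    PAN-FPN neck, ELC grouped conv + cost law
src/safi/head.py    stock and shared-conv detection heads, decode + NMS
src/safi/losses.py  IoU / PIoU / PIoUv2 / CIoU and the composite training loss
src/safi/assigner.py  task-aligned anchor assignment
src/safi/assembly.py  variant construction, parameter/FLOP accounting, ablation grid
src/safi/data.py    synthetic scenes, splits, augmentation, mosaic, VOC/YOLO I/O
src/safi/train.py   training loop (SGD, warmup + linear decay), evaluation, FPS
src/safi/metrics.py precision / recall / AP (all-point envelope) / mAP@0.5
src/safi/cli.py     `safi` entry point
configs/            calibrated model configs (the repository constants)
```

Notes on conventions: FLOPs are 2x convolution multiply-accumulates at the
stated input size; parameter counts are trainable scalars only; box
coordinates are 0-based continuous pixels, xyxy, origin top-left.
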