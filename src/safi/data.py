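"""Synthetic field scenes, dataset splits, augmentation, and label I/O.

The scene generator stands in for the (non-public) field photographs: a
textured green background, small elliptical two-class targets (class 0 =
blooming, warm orange-red; class 1 = decay, dull brown), variable
brightness/saturation, and foreground-coloured occluders drawn over objects
at a requested per-object fraction.  Objects occluded by more than 70% are
drawn but omitted from the label list, mirroring the annotation rule of the
source dataset.

Coordinate convention: 0-based continuous pixels, xyxy, origin top-left.
YOLO label lines use normalised ``cx cy w h``.
"""
from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .losses import BoundingBox

__all__ = [
    "CLASS_NAMES", "SceneObject", "SceneSpec", "generate_scene",
    "generate_dataset", "split_dataset", "augment", "rotate_image_and_boxes",
    "mosaic", "read_voc_xml", "write_voc_xml", "read_yolo_txt",
    "write_yolo_txt", "yolo_line_to_box", "box_to_yolo_line",
]

CLASS_NAMES = ("Safflower-B", "Safflower-D")
OCCLUSION_LABEL_LIMIT = 0.70

# class base colours (RGB): blooming = warm orange-red, decay = dull brown
_CLASS_COLORS = {0: (225, 90, 35), 1: (125, 85, 45)}


@dataclass(frozen=True)
class SceneObject:
    class_id: int
    cx: float
    cy: float
    ax: float            # semi-axis along orientation
    ay: float
    angle: float         # radians
    occlusion_fraction: float = 0.0

    def __post_init__(self):
        if self.class_id not in (0, 1):
            raise ValueError("class_id must be 0 or 1")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple = (320, 320)   # (W, H)
    objects: tuple = ()
    brightness: float = 1.0
    saturation: float = 1.0
    seed: int = 0

    @classmethod
    def random(cls, seed: int, n_objects: int = 3, image_size=(320, 320),
               occlusion_range=(0.0, 0.5), object_scale=(0.05, 0.12)):
        """Sample a scene layout deterministically from ``seed``."""
        rng = np.random.default_rng(seed)
        w, h = image_size
        objs = []
        for _ in range(n_objects):
            ax = rng.uniform(*object_scale) * min(w, h)
            ay = ax * rng.uniform(0.6, 1.0)
            objs.append(SceneObject(
                class_id=int(rng.integers(0, 2)),
                cx=float(rng.uniform(ax * 1.5, w - ax * 1.5)),
                cy=float(rng.uniform(ay * 1.5, h - ay * 1.5)),
                ax=float(ax), ay=float(ay),
                angle=float(rng.uniform(0, math.pi)),
                occlusion_fraction=float(rng.uniform(*occlusion_range)),
            ))
        return cls(
            image_size=tuple(image_size), objects=tuple(objs),
            brightness=float(rng.uniform(0.8, 1.2)),
            saturation=float(rng.uniform(0.8, 1.2)),
            seed=seed,
        )


def _ellipse_mask(w, h, obj: SceneObject) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - obj.cx, yy - obj.cy
    c, s = math.cos(obj.angle), math.sin(obj.angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / obj.ax) ** 2 + (v / obj.ay) ** 2 <= 1.0


def _textured_background(rng, w, h):
    base = np.array([58, 95, 48], dtype=float)  # foliage green
    tex = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 6.0)
    tex = tex / (np.abs(tex).max() + 1e-9)
    img = base[None, None, :] + tex[..., None] * np.array([18, 28, 14])
    speck = rng.uniform(-10, 10, (h, w, 1))
    return np.clip(img + speck, 0, 255)


def generate_scene(spec: SceneSpec):
    """Render a scene; returns (uint8 HxWx3 image, list of BoundingBox).

    Deterministic in ``spec`` (including its seed).  Objects whose occluded
    fraction exceeds 70% appear in the image but not in the labels.
    """
    w, h = spec.image_size
    rng = np.random.default_rng(spec.seed)
    img = _textured_background(rng, w, h)
    labels = []
    for obj in spec.objects:
        mask = _ellipse_mask(w, h, obj)
        if not mask.any():
            continue
        color = np.array(_CLASS_COLORS[obj.class_id], dtype=float)
        color = color + rng.uniform(-15, 15, 3)
        # radial shading for a little realism
        yy, xx = np.nonzero(mask)
        rad = np.hypot(xx - obj.cx, yy - obj.cy)
        shade = 1.0 - 0.35 * (rad / (rad.max() + 1e-9))
        img[yy, xx] = np.clip(color[None, :] * shade[:, None], 0, 255)

        occluded = _draw_occluder(img, mask, obj, rng)
        x1, x2 = xx.min(), xx.max() + 1
        y1, y2 = yy.min(), yy.max() + 1
        if occluded <= OCCLUSION_LABEL_LIMIT and x2 - x1 > 1 and y2 - y1 > 1:
            labels.append(BoundingBox(obj.class_id, float(x1), float(y1),
                                      float(x2), float(y2)))
    # lighting
    img = _apply_brightness_saturation(img, spec.brightness, spec.saturation)
    img = np.clip(img + rng.normal(0, 2.0, img.shape), 0, 255)
    return img.astype(np.uint8), labels


def _draw_occluder(img, mask, obj: SceneObject, rng) -> float:
    """Cover ~obj.occlusion_fraction of the object with a branch-like bar.

    Returns the realised covered fraction of the object's pixels.
    """
    target = obj.occlusion_fraction
    if target <= 0:
        return 0.0
    yy, xx = np.nonzero(mask)
    total = len(yy)
    order = np.argsort(yy, kind="stable")  # cover from the top downward
    n_cover = int(round(target * total))
    if n_cover == 0:
        return 0.0
    covered = order[:n_cover]
    cut_y = yy[covered].max()
    band = mask & (np.arange(img.shape[0])[:, None] <= cut_y)
    by, bx = np.nonzero(band)
    # occluder drawn slightly wider than the object band ("branches/leaves")
    pad = 2
    y1o = max(by.min() - pad, 0)
    y2o = min(by.max() + pad + 1, img.shape[0])
    x1o = max(bx.min() - pad, 0)
    x2o = min(bx.max() + pad + 1, img.shape[1])
    occ_color = np.array([45, 75, 35], dtype=float) + rng.uniform(-8, 8, 3)
    img[y1o:y2o, x1o:x2o] = np.clip(occ_color, 0, 255)
    return band.sum() / total


def _apply_brightness_saturation(img, brightness, saturation):
    out = img * brightness
    if saturation != 1.0:
        gray = out.mean(axis=2, keepdims=True)
        out = gray + (out - gray) * saturation
    return np.clip(out, 0, 255)


# ---------------------------------------------------------------------------
# dataset generation / split
# ---------------------------------------------------------------------------

def generate_dataset(n: int, out_dir, seed: int = 0, image_size=(320, 320),
                     n_objects=(1, 5)):
    """Write ``n`` scenes (PNG + VOC XML + YOLO txt + dataset YAML)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels_voc").mkdir(exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    stems = []
    for i in range(n):
        k = int(rng.integers(n_objects[0], n_objects[1] + 1))
        spec = SceneSpec.random(seed=int(rng.integers(0, 2**31 - 1)),
                                n_objects=k, image_size=image_size)
        img, labels = generate_scene(spec)
        stem = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / f"{stem}.png")
        write_voc_xml(out / "labels_voc" / f"{stem}.xml", labels,
                      image_size=image_size, filename=f"{stem}.png")
        write_yolo_txt(out / "labels" / f"{stem}.txt", labels, image_size)
        stems.append(stem)
    with open(out / "dataset.yaml", "w") as fh:
        fh.write(f"path: {out.resolve()}\nimages: images\nlabels: labels\n")
        fh.write("names:\n")
        for i, name in enumerate(CLASS_NAMES):
            fh.write(f"  {i}: {name}\n")
    return stems


def split_dataset(items, ratios=(7, 2, 1), seed: int = 0):
    """Deterministic disjoint split with exact proportional counts.

    Any remainder from non-divisible sizes goes to the training set.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    items = list(items)
    n = len(items)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    total = sum(ratios)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    n_train = n - n_val - n_test
    shuffled = [items[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :])


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUG_OPS = ("brightness", "saturation", "rotation", "gaussian_noise")
# magnitude ranges (the source work names the ops but not their ranges)
BRIGHTNESS_RANGE = (0.6, 1.4)
SATURATION_RANGE = (0.6, 1.4)
ROTATION_RANGE_DEG = 15.0
NOISE_SIGMA_MAX = 0.05  # fraction of dynamic range


def rotate_image_and_boxes(image: np.ndarray, boxes, angle_deg: float):
    """Rotate about the image centre; re-fit axis-aligned boxes, clip, drop
    boxes that degenerate to zero area."""
    h, w = image.shape[:2]
    pil = Image.fromarray(image)
    rotated = np.asarray(pil.rotate(angle_deg, resample=Image.BILINEAR,
                                    fillcolor=(58, 95, 48)))
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    cx, cy = w / 2.0, h / 2.0  # PIL rotates about the geometric centre
    out_boxes, dropped = [], []
    for b in boxes:
        corners = np.array([[b.x1, b.y1], [b.x2, b.y1], [b.x1, b.y2], [b.x2, b.y2]])
        dx, dy = corners[:, 0] - cx, corners[:, 1] - cy
        # PIL rotates counter-clockwise for positive angles (y axis down)
        nx = cx + dx * c + dy * s
        ny = cy - dx * s + dy * c
        x1, y1 = max(nx.min(), 0.0), max(ny.min(), 0.0)
        x2, y2 = min(nx.max(), float(w)), min(ny.max(), float(h))
        if x2 - x1 > 1e-6 and y2 - y1 > 1e-6:
            out_boxes.append(BoundingBox(b.class_id, x1, y1, x2, y2))
        else:
            dropped.append(b)
    return rotated, out_boxes, dropped


def augment(image: np.ndarray, boxes, ops=AUG_OPS, seed: int = 0):
    """Apply the selected photometric/geometric ops, seeded.

    Photometric ops leave boxes untouched; rotation re-fits them.  Returns
    (image, boxes).
    """
    unknown = set(ops) - set(AUG_OPS)
    if unknown:
        raise ValueError(f"unknown augment ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    img = image.astype(float)
    boxes = list(boxes)
    if "brightness" in ops:
        img = np.clip(img * rng.uniform(*BRIGHTNESS_RANGE), 0, 255)
    if "saturation" in ops:
        img = _apply_brightness_saturation(img, 1.0, rng.uniform(*SATURATION_RANGE))
    if "rotation" in ops:
        angle = rng.uniform(-ROTATION_RANGE_DEG, ROTATION_RANGE_DEG)
        img8 = np.clip(img, 0, 255).astype(np.uint8)
        img, boxes, _ = rotate_image_and_boxes(img8, boxes, angle)
        img = img.astype(float)
    if "gaussian_noise" in ops:
        sigma = rng.uniform(0, NOISE_SIGMA_MAX) * 255.0
        img = np.clip(img + rng.normal(0, sigma, img.shape), 0, 255)
    return img.astype(np.uint8), boxes


def mosaic(images4, boxes4, out_size, seed: int = 0):
    """Compose four images into one around a random junction point.

    Each quadrant's source is mapped by that quadrant's (anisotropic)
    scale-and-translate affine; boxes are remapped by the same affine and
    clipped.  Returns (image, boxes).
    """
    if len(images4) != 4 or len(boxes4) != 4:
        raise ValueError("mosaic requires exactly 4 images and 4 box lists")
    if isinstance(out_size, int):
        out_size = (out_size, out_size)
    ow, oh = out_size
    rng = np.random.default_rng(seed)
    jx = int(rng.uniform(0.25, 0.75) * ow)
    jy = int(rng.uniform(0.25, 0.75) * oh)
    rects = [(0, 0, jx, jy), (jx, 0, ow, jy), (0, jy, jx, oh), (jx, jy, ow, oh)]
    canvas = np.zeros((oh, ow, 3), dtype=np.uint8)
    out_boxes = []
    for img, boxes, (x1, y1, x2, y2) in zip(images4, boxes4, rects):
        qw, qh = x2 - x1, y2 - y1
        if qw <= 0 or qh <= 0:
            continue
        h, w = img.shape[:2]
        resized = np.asarray(Image.fromarray(img).resize((qw, qh), Image.BILINEAR))
        canvas[y1:y2, x1:x2] = resized
        sx, sy = qw / w, qh / h
        for b in boxes:
            nx1 = max(b.x1 * sx + x1, x1)
            ny1 = max(b.y1 * sy + y1, y1)
            nx2 = min(b.x2 * sx + x1, x2)
            ny2 = min(b.y2 * sy + y1, y2)
            if nx2 - nx1 > 1e-6 and ny2 - ny1 > 1e-6:
                out_boxes.append(BoundingBox(b.class_id, nx1, ny1, nx2, ny2))
    return canvas, out_boxes


# ---------------------------------------------------------------------------
# label I/O
# ---------------------------------------------------------------------------

def write_voc_xml(path, boxes, image_size, filename="image.png"):
    w, h = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = CLASS_NAMES[b.class_id]
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = f"{b.x1:.2f}"
        ET.SubElement(bb, "ymin").text = f"{b.y1:.2f}"
        ET.SubElement(bb, "xmax").text = f"{b.x2:.2f}"
        ET.SubElement(bb, "ymax").text = f"{b.y2:.2f}"
    ET.ElementTree(root).write(path)


def read_voc_xml(path):
    """Returns (boxes, (W, H)).  Raises ValueError naming file and field."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise ValueError(f"{path}: malformed XML ({e})") from e
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing <size> element")
    w = int(float(size.findtext("width")))
    h = int(float(size.findtext("height")))
    boxes = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name not in CLASS_NAMES:
            raise ValueError(f"{path}: unknown class name {name!r}")
        bb = obj.find("bndbox")
        try:
            coords = [float(bb.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax")]
        except (TypeError, AttributeError) as e:
            raise ValueError(f"{path}: incomplete <bndbox> for {name!r}") from e
        x1, y1, x2, y2 = coords
        if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
            raise ValueError(
                f"{path}: out-of-range bndbox ({x1}, {y1}, {x2}, {y2}) "
                f"for image {w}x{h}")
        boxes.append(BoundingBox(CLASS_NAMES.index(name), x1, y1, x2, y2))
    return boxes, (w, h)


def box_to_yolo_line(b: BoundingBox, image_size) -> str:
    w, h = image_size
    cx = (b.x1 + b.x2) / 2.0 / w
    cy = (b.y1 + b.y2) / 2.0 / h
    bw = (b.x2 - b.x1) / w
    bh = (b.y2 - b.y1) / h
    return f"{b.class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}"


def yolo_line_to_box(line: str, image_size) -> BoundingBox:
    parts = line.split()
    if len(parts) != 5:
        raise ValueError(f"bad YOLO label line: {line!r}")
    cid = int(parts[0])
    cx, cy, bw, bh = map(float, parts[1:])
    w, h = image_size
    return BoundingBox(cid,
                       (cx - bw / 2) * w, (cy - bh / 2) * h,
                       (cx + bw / 2) * w, (cy + bh / 2) * h)


def write_yolo_txt(path, boxes, image_size):
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(box_to_yolo_line(b, image_size) + "\n")


def read_yolo_txt(path, image_size):
    boxes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                boxes.append(yolo_line_to_box(line, image_size))
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{ln}: {e}") from e
    return boxes
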