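"""Readers and writers for the annotation file formats.

Internally boxes are 0-based with inclusive max corners (pixel width =
xmax - xmin + 1).  The YOLO text formats are normalized center/size with the
half-open convention, so the conversion applies the +1 width rule exactly
once, here and nowhere else.  Floats are written with 6 decimals; round
trips are lossless to that precision.

Formats:

* YOLO box txt — ``class cx cy w h [score]`` per line, normalized.
* YOLO segmentation txt — ``class x1 y1 x2 y2 ... [score]`` per line,
  normalized polygon vertices (even-odd fill on rasterization).
* 16-bit PNG instance label maps — background 0, instance i -> i+1.
* Prompt JSON — ``{"positive": [[x, y]...], "negative": [...], "boxes":
  [[xmin, ymin, xmax, ymax]...]}`` in absolute pixel coordinates.
* Metrics JSON — versioned flat schema of a MetricsReport.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from PIL import Image
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .geometry import BBox, InstanceMask
from .annotation_loop import PromptSet
from .metrics import MetricsReport

__all__ = [
    "FormatError",
    "read_yolo_boxes",
    "write_yolo_boxes",
    "read_yolo_polygons",
    "write_yolo_polygons",
    "mask_to_polygon",
    "polygon_to_mask",
    "read_instance_png",
    "write_instance_png",
    "read_prompts",
    "write_prompts",
    "write_metrics_json",
    "read_image",
    "write_image",
    "RunConfig",
]

METRICS_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed annotation file; message carries file:line."""


def _parse_floats(parts: Sequence[str], path, lineno: int) -> list[float]:
    try:
        return [float(p) for p in parts]
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: {e}") from None


# ---------------------------------------------------------------------------
# YOLO boxes


def write_yolo_boxes(path, boxes: Sequence[BBox], image_size: tuple[int, int]) -> None:
    """``image_size`` is (W, H)."""
    w, h = image_size
    lines = []
    for b in boxes:
        bw = (b.xmax - b.xmin + 1) / w
        bh = (b.ymax - b.ymin + 1) / h
        cx = (b.xmin + b.xmax + 1) / 2.0 / w
        cy = (b.ymin + b.ymax + 1) / 2.0 / h
        parts = [str(b.class_id)] + [f"{v:.6f}" for v in (cx, cy, bw, bh)]
        if b.score is not None:
            parts.append(f"{b.score:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_boxes(path, image_size: tuple[int, int]) -> list[BBox]:
    w, h = image_size
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise FormatError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        vals = _parse_floats(parts, path, lineno)
        cls = int(vals[0])
        cx, cy, bw, bh = vals[1:5]
        score = vals[5] if len(vals) == 6 else None
        xmin = cx * w - bw * w / 2.0
        ymin = cy * h - bh * h / 2.0
        boxes.append(
            BBox(
                xmin=round(xmin, 6), ymin=round(ymin, 6),
                xmax=round(xmin + bw * w - 1, 6), ymax=round(ymin + bh * h - 1, 6),
                score=score, class_id=cls,
            )
        )
    return boxes


# ---------------------------------------------------------------------------
# YOLO segmentation polygons


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """External contour of the largest connected region, as (N, 2) xy pixel
    coordinates."""
    contours = measure.find_contours(np.asarray(mask, float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)  # (row, col)
    return contour[:, ::-1].copy()  # -> (x, y)


def polygon_to_mask(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (N, 2) xy polygon into a boolean (H, W) mask."""
    xy = np.asarray(xy, float)
    rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def write_yolo_polygons(
    path, masks: Sequence[InstanceMask], image_size: tuple[int, int],
    scores: Optional[Sequence[float]] = None,
) -> None:
    w, h = image_size
    lines = []
    for i, m in enumerate(masks):
        xy = mask_to_polygon(m.mask)
        parts = [str(m.class_id)]
        for x, y in xy:
            parts.append(f"{x / w:.6f}")
            parts.append(f"{y / h:.6f}")
        if scores is not None:
            parts.append(f"{scores[i]:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_polygons(
    path, image_size: tuple[int, int], with_scores: bool = False
) -> Union[list[InstanceMask], tuple[list[InstanceMask], list[Optional[float]]]]:
    w, h = image_size
    masks, scores = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        vals = _parse_floats(parts, path, lineno)
        cls = int(vals[0])
        rest = vals[1:]
        score = None
        if len(rest) % 2 == 1:  # odd tail -> trailing confidence
            score = rest[-1]
            rest = rest[:-1]
        if len(rest) < 6:
            raise FormatError(f"{path}:{lineno}: polygon needs at least 3 vertices")
        xy = np.array(rest, float).reshape(-1, 2) * (w, h)
        masks.append(InstanceMask(polygon_to_mask(xy, (h, w)), instance_id=len(masks), class_id=cls))
        scores.append(score)
    if with_scores:
        return masks, scores
    return masks


# ---------------------------------------------------------------------------
# Instance label maps and images


def write_instance_png(path, masks: Sequence[InstanceMask], shape: tuple[int, int]) -> None:
    label = np.zeros(shape, np.uint16)
    for i, m in enumerate(masks):
        label[m.mask] = i + 1
    Image.fromarray(label).save(path)  # uint16 -> 16-bit grayscale PNG


def read_instance_png(path) -> list[InstanceMask]:
    label = np.array(Image.open(path), dtype=np.uint16)
    masks = []
    for i in range(1, int(label.max()) + 1):
        m = label == i
        if m.any():
            masks.append(InstanceMask(m, instance_id=len(masks), class_id=0))
    return masks


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray((np.clip(image, 0, 1) * 255).round().astype(np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), np.float32) / 255.0


# ---------------------------------------------------------------------------
# Prompts, metrics, run config


def write_prompts(path, prompts: PromptSet) -> None:
    payload = {
        "positive": [[float(x), float(y)] for x, y in prompts.positive],
        "negative": [[float(x), float(y)] for x, y in prompts.negative],
        "boxes": [[b.xmin, b.ymin, b.xmax, b.ymax] for b in prompts.boxes],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_prompts(path) -> PromptSet:
    d = json.loads(Path(path).read_text())
    return PromptSet(
        positive=[tuple(p) for p in d.get("positive", [])],
        negative=[tuple(p) for p in d.get("negative", [])],
        boxes=[BBox(*b) for b in d.get("boxes", [])],
    )


def write_metrics_json(path, report: MetricsReport) -> None:
    payload = {"schema_version": METRICS_SCHEMA_VERSION, **report.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


@dataclasses.dataclass
class RunConfig:
    """Resolved run parameters; every CLI run writes this beside its outputs
    so results are reproducible from the file alone."""

    seed: int = 0
    epsilon: float = 2.0
    max_iterations: int = 5
    match_iou: float = 0.5
    iou_thresh: float = 0.5
    miou_floor: float = 0.75
    conf_thresh: float = 0.3
    nms_iou: float = 0.5
    reg_max: int = 24
    num_prototypes: int = 32
    log_level: str = "INFO"
    # reference training constants, documentation only (not used at inference)
    train_batch_size: int = 120
    train_momentum: float = 0.937

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
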