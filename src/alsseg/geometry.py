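"""Shared geometric primitives: axis-aligned boxes and binary instance masks.

Boxes use 0-based pixel coordinates with an *inclusive* max corner: the box
(xmin, ymin, xmax, ymax) contains the pixel columns xmin..xmax and rows
ymin..ymax, so its pixel width is ``xmax - xmin + 1``.  This is the natural
convention for a minimum bounding box computed as a min/max over member
pixels.  Conversion to half-open or normalized conventions happens only at
file-format boundaries (see :mod:`alsseg.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["BBox", "InstanceMask", "box_iou", "mask_iou"]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, inclusive max corner.  Coordinates may be fractional
    (e.g. after center-scaling); pixel-area computations use the +1 rule."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: Optional[float] = None
    class_id: int = 0

    def __post_init__(self) -> None:
        if self.xmax < self.xmin or self.ymax < self.ymin:
            raise ValueError(f"degenerate box {self!r}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin + 1

    @property
    def height(self) -> float:
        return self.ymax - self.ymin + 1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0

    def clip(self, width: int, height: int) -> "BBox":
        """Clip to an image of the given size (pixels 0..width-1, 0..height-1)."""
        return replace(
            self,
            xmin=min(max(self.xmin, 0), width - 1),
            ymin=min(max(self.ymin, 0), height - 1),
            xmax=min(max(self.xmax, 0), width - 1),
            ymax=min(max(self.ymax, 0), height - 1),
        )

    def round(self) -> "BBox":
        return replace(
            self,
            xmin=float(np.floor(self.xmin + 0.5)),
            ymin=float(np.floor(self.ymin + 0.5)),
            xmax=float(np.floor(self.xmax + 0.5)),
            ymax=float(np.floor(self.ymax + 0.5)),
        )

    def translate(self, dx: float, dy: float) -> "BBox":
        return replace(
            self,
            xmin=self.xmin + dx,
            ymin=self.ymin + dy,
            xmax=self.xmax + dx,
            ymax=self.ymax + dy,
        )

    def scale_about_center(self, factor: float) -> "BBox":
        """Scale width and height by ``factor`` about the box center using the
        continuous (max - min) extent."""
        cx, cy = self.center
        hw = (self.xmax - self.xmin) * factor / 2.0
        hh = (self.ymax - self.ymin) * factor / 2.0
        return replace(self, xmin=cx - hw, ymin=cy - hh, xmax=cx + hw, ymax=cy + hh)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass
class InstanceMask:
    """A binary pixel mask at image resolution for one instance."""

    mask: np.ndarray  # bool (H, W)
    instance_id: int = 0
    class_id: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def box_iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes with inclusive pixel areas."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin) + 1
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin) + 1
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return float(inter / union)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(inter / union)
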