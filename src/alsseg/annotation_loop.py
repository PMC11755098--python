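"""Iterative annotation bootstrapping against pluggable backends.

The pipeline alternates between a promptable segmenter (points/boxes in,
instance masks out — the role a large zero-shot segmentation model plays in
production) and a detector that is retrained each round on the current boxes.
A round turns boxes into refined masks, masks into minimum bounding boxes,
and feeds those back as the next round's training data.  Convergence is
declared when consecutive rounds' boxes stop moving.

Box-change metric: boxes of consecutive rounds are greedily matched by
descending IoU (at >= ``match_iou``); the delta is the mean over matched
pairs of the maximum absolute corner-coordinate difference, and any
unmatched box on either side forces +inf (an appearing or disappearing
instance is a change, not noise).

Images annotated from manual prompts (and any manually corrected ones) are
flagged *fine* and are never overwritten by detector output.
"""

from __future__ import annotations

import logging
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import BBox, InstanceMask, box_iou
from . import metrics as M

logger = logging.getLogger(__name__)

__all__ = [
    "PromptSet",
    "AnnotationRound",
    "ConvergenceConfig",
    "SegmenterBackend",
    "DetectorBackend",
    "segment_with_prompts",
    "minimum_bounding_box",
    "detect",
    "refine_masks",
    "round_delta",
    "run_loop",
    "apply_corrections",
]


@dataclass
class PromptSet:
    """Guidance for a promptable segmenter: positive points (inside targets),
    negative points (outside), and/or boxes."""

    positive: list[tuple[float, float]] = field(default_factory=list)
    negative: list[tuple[float, float]] = field(default_factory=list)
    boxes: list[BBox] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.positive or self.negative or self.boxes)


@dataclass
class AnnotationRound:
    """State after one round: per-image box and mask sets plus fine flags."""

    iteration: int
    boxes: dict[int, list[BBox]] = field(default_factory=dict)
    masks: dict[int, list[InstanceMask]] = field(default_factory=dict)
    fine: dict[int, bool] = field(default_factory=dict)

    def validate(self) -> None:
        for iid in self.boxes:
            if len(self.boxes[iid]) != len(self.masks.get(iid, [])):
                raise ValueError(f"image {iid}: box/mask count mismatch")


@dataclass(frozen=True)
class ConvergenceConfig:
    epsilon: float = 2.0  # pixels
    match_iou: float = 0.5
    max_iterations: int = 5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class SegmenterBackend(ABC):
    """Contract for a promptable segmenter (deterministic given its seed)."""

    @abstractmethod
    def segment(self, image_id: int, image: np.ndarray, prompts: PromptSet) -> list[InstanceMask]:
        ...


class DetectorBackend(ABC):
    """Contract for a trainable detector (predict deterministic after train,
    given its seed)."""

    @abstractmethod
    def train(self, labeled: Sequence[tuple[int, np.ndarray, list[BBox]]]) -> None:
        ...

    @abstractmethod
    def predict(self, image_id: int, image: np.ndarray) -> list[BBox]:
        ...

    @property
    @abstractmethod
    def is_trained(self) -> bool:
        ...


# ---------------------------------------------------------------------------
# Operations


def segment_with_prompts(
    seg: SegmenterBackend, image_id: int, image: np.ndarray, prompts: PromptSet
) -> list[InstanceMask]:
    if prompts.is_empty:
        raise ValueError("prompt set is empty")
    return seg.segment(image_id, image, prompts)


def minimum_bounding_box(mask: InstanceMask) -> BBox:
    """Tightest axis-aligned box over the foreground pixels (inclusive
    min/max of member pixel coordinates)."""
    if mask.is_empty:
        raise ValueError("cannot compute a bounding box of an empty mask")
    ys, xs = np.nonzero(mask.mask)
    return BBox(
        xmin=float(xs.min()), ymin=float(ys.min()),
        xmax=float(xs.max()), ymax=float(ys.max()),
        class_id=mask.class_id,
    )


def detect(det: DetectorBackend, image_id: int, image: np.ndarray) -> list[BBox]:
    if not det.is_trained:
        raise RuntimeError("detector has not been trained")
    return det.predict(image_id, image)


def refine_masks(
    seg: SegmenterBackend, image_id: int, image: np.ndarray, boxes: Sequence[BBox]
) -> list[InstanceMask]:
    """One refined mask per box prompt; out-of-bounds boxes are clipped with
    a warning."""
    h, w = image.shape[:2]
    clipped = []
    for b in boxes:
        if b.xmin < 0 or b.ymin < 0 or b.xmax > w - 1 or b.ymax > h - 1:
            logger.warning("image %s: box %s outside bounds, clipping", image_id, b.as_tuple())
            b = b.clip(w, h)
        clipped.append(b)
    masks: list[InstanceMask] = []
    for b in clipped:
        got = seg.segment(image_id, image, PromptSet(boxes=[b]))
        if got:
            masks.append(got[0])
        else:
            masks.append(InstanceMask(np.zeros((h, w), bool)))
    return masks


def round_delta(
    prev: AnnotationRound, next: AnnotationRound, match_iou: float = 0.5
) -> float:
    """Mean matched max-corner deviation between two rounds' boxes; +inf when
    any box is unmatched.  Symmetric; 0 iff box sets coincide under matching."""
    image_ids = set(prev.boxes) | set(next.boxes)
    deviations: list[float] = []
    for iid in image_ids:
        a = list(prev.boxes.get(iid, []))
        b = list(next.boxes.get(iid, []))
        pairs = []
        for i, ba in enumerate(a):
            for j, bb in enumerate(b):
                v = box_iou(ba, bb)
                if v >= match_iou:
                    pairs.append((v, i, j))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for v, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            ba, bb = a[i], b[j]
            deviations.append(
                max(
                    abs(ba.xmin - bb.xmin), abs(ba.ymin - bb.ymin),
                    abs(ba.xmax - bb.xmax), abs(ba.ymax - bb.ymax),
                )
            )
        if len(used_a) != len(a) or len(used_b) != len(b):
            return math.inf
    if not deviations:
        return 0.0
    return float(np.mean(deviations))


def apply_corrections(
    round_: AnnotationRound,
    seg: Optional[SegmenterBackend] = None,
    images: Optional[Mapping[int, np.ndarray]] = None,
    additions: Optional[Mapping[int, PromptSet]] = None,
    edits: Optional[Mapping[tuple[int, int], tuple[float, float, float]]] = None,
) -> AnnotationRound:
    """Targeted manual corrections after iteration.

    ``additions`` supply prompts for missed instances (low recall): each
    prompt set is segmented and appended.  ``edits`` fix false or misplaced
    boxes (low precision): (image, box index) -> (dx, dy, scale) translates
    the box and scales its width/height about the center, then clips; the
    refined mask is re-segmented from the edited box when a segmenter is
    available.  Corrected images are flagged fine.
    """
    new = AnnotationRound(
        iteration=round_.iteration,
        boxes={k: list(v) for k, v in round_.boxes.items()},
        masks={k: list(v) for k, v in round_.masks.items()},
        fine=dict(round_.fine),
    )
    if additions:
        if seg is None or images is None:
            raise ValueError("additions require a segmenter and images")
        for iid, prompts in additions.items():
            masks = segment_with_prompts(seg, iid, images[iid], prompts)
            new.masks.setdefault(iid, []).extend(masks)
            new.boxes.setdefault(iid, []).extend(minimum_bounding_box(m) for m in masks)
            new.fine[iid] = True
    if edits:
        for (iid, box_id), (dx, dy, scale) in edits.items():
            try:
                box = new.boxes[iid][box_id]
            except (KeyError, IndexError):
                raise KeyError(f"no box {box_id} on image {iid}") from None
            edited = box.translate(dx, dy).scale_about_center(scale)
            if images is not None and iid in images:
                h, w = images[iid].shape[:2]
                edited = edited.clip(w, h)
            new.boxes[iid][box_id] = edited
            if seg is not None and images is not None and iid in images:
                new.masks[iid][box_id] = refine_masks(seg, iid, images[iid], [edited])[0]
            new.fine[iid] = True
    return new


def _round_miou(round_: AnnotationRound, ground_truth: Mapping[int, list[InstanceMask]]) -> float:
    """Pooled single-per-class pixel mIoU of a round's masks against truth."""
    classes = sorted(
        {m.class_id for ms in ground_truth.values() for m in ms}
        | {m.class_id for ms in round_.masks.values() for m in ms}
    )
    pred: dict[int, list[np.ndarray]] = {c: [] for c in classes}
    gt: dict[int, list[np.ndarray]] = {c: [] for c in classes}
    for iid, gt_masks in ground_truth.items():
        shape = gt_masks[0].mask.shape if gt_masks else None
        if shape is None:
            continue
        for c in classes:
            pm = np.zeros(shape, bool)
            for m in round_.masks.get(iid, []):
                if m.class_id == c:
                    pm |= m.mask
            gm = np.zeros(shape, bool)
            for m in gt_masks:
                if m.class_id == c:
                    gm |= m.mask
            pred[c].append(pm)
            gt[c].append(gm)
    return M.miou(
        {c: np.stack(v) for c, v in pred.items() if v},
        {c: np.stack(v) for c, v in gt.items() if v},
    )


def run_loop(
    seg: SegmenterBackend,
    det: DetectorBackend,
    images: Mapping[int, np.ndarray],
    initial_prompts: Mapping[int, PromptSet],
    cfg: ConvergenceConfig = ConvergenceConfig(),
    ground_truth: Optional[Mapping[int, list[InstanceMask]]] = None,
) -> tuple[AnnotationRound, list[dict]]:
    """Run the full bootstrapping loop.

    Round 0 annotates the seeded subset from its prompts (flagged fine).
    Each subsequent iteration retrains the detector on all current labels,
    re-annotates every non-fine image (detect -> refine -> re-box), and
    stops when the round delta drops below epsilon or ``max_iterations`` is
    reached.  Returns the final round and a per-round log.
    """
    if not initial_prompts:
        raise ValueError("at least one seed image with prompts is required")
    current = AnnotationRound(iteration=0)
    for iid, prompts in initial_prompts.items():
        masks = segment_with_prompts(seg, iid, images[iid], prompts)
        current.masks[iid] = masks
        current.boxes[iid] = [minimum_bounding_box(m) for m in masks]
        current.fine[iid] = True
    log: list[dict] = []
    entry = {"iteration": 0, "delta": None,
             "n_images": len(current.boxes),
             "n_boxes": sum(len(v) for v in current.boxes.values())}
    if ground_truth is not None:
        entry["miou"] = _round_miou(current, ground_truth)
    log.append(entry)
    for t in range(1, cfg.max_iterations + 1):
        labeled = [(iid, images[iid], current.boxes[iid]) for iid in sorted(current.boxes)]
        det.train(labeled)
        nxt = AnnotationRound(iteration=t, fine=dict(current.fine))
        for iid in sorted(images):
            if current.fine.get(iid):
                nxt.boxes[iid] = list(current.boxes[iid])
                nxt.masks[iid] = list(current.masks[iid])
                continue
            pred = detect(det, iid, images[iid])
            masks = refine_masks(seg, iid, images[iid], pred)
            keep = [m for m in masks if not m.is_empty]
            nxt.masks[iid] = keep
            nxt.boxes[iid] = [minimum_bounding_box(m) for m in keep]
        delta = round_delta(current, nxt, cfg.match_iou)
        entry = {"iteration": t, "delta": delta,
                 "n_images": len(nxt.boxes),
                 "n_boxes": sum(len(v) for v in nxt.boxes.values())}
        if ground_truth is not None:
            entry["miou"] = _round_miou(nxt, ground_truth)
        log.append(entry)
        current = nxt
        if delta < cfg.epsilon or math.isinf(cfg.epsilon):
            # an infinite tolerance accepts any change, including +inf
            logger.info("converged at iteration %d (delta %.3f < %.3f)", t, delta, cfg.epsilon)
            break
    return current, log
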