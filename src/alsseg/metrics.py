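"""Box and mask evaluation: P/R/F1, AP and mAP, mIoU, and operating-point
selection.

Conventions, stated once and used everywhere:

* IoU on boxes uses inclusive pixel areas (width = xmax - xmin + 1).
* Matching is greedy in descending score: each detection claims the
  highest-IoU still-unmatched ground truth with IoU >= threshold; equal
  scores are broken by input index.
* P, R and F1 use the 0/0 -> 0 convention.
* AP integrates the all-point precision envelope over recall (precision at
  each recall replaced by the maximum precision at any recall >= it).
* mAP is the unweighted mean of per-class APs; classes without ground truth
  have undefined AP and are excluded (and logged).
* mIoU pools pixels per class over the whole evaluated image set, then
  averages over classes present in prediction or ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .geometry import BBox, InstanceMask, box_iou, mask_iou

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "MatchCounts",
    "PRCurve",
    "MetricsReport",
    "iou",
    "match",
    "precision_recall_f1",
    "average_precision",
    "mean_ap",
    "miou",
    "max_f1_threshold",
    "filtered_miou_report",
    "evaluate",
]


@dataclass
class Detection:
    image_id: int
    class_id: int
    score: float
    bbox: BBox
    mask: Optional[InstanceMask] = None


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    class_id: int = 0


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    ap: float
    map50: float
    map_range: float
    miou: float
    n_classes: int
    operating_threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def iou(a, b) -> float:
    """IoU of two boxes or two masks; mixing kinds is an error."""
    a_box, b_box = isinstance(a, BBox), isinstance(b, BBox)
    if a_box and b_box:
        return box_iou(a, b)
    if a_box != b_box:
        raise TypeError("cannot compute IoU between a box and a mask")
    am = a.mask if isinstance(a, InstanceMask) else np.asarray(a)
    bm = b.mask if isinstance(b, InstanceMask) else np.asarray(b)
    return mask_iou(am, bm)


def _pair_iou(det: Detection, gt: Detection, kind: str) -> float:
    if kind == "box":
        return box_iou(det.bbox, gt.bbox)
    if kind == "mask":
        if det.mask is None or gt.mask is None:
            raise ValueError("mask matching requires masks on both sides")
        return mask_iou(det.mask.mask, gt.mask.mask)
    raise ValueError(f"unknown kind {kind!r}")


def match(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_thresh: float = 0.5,
    kind: str = "box",
) -> tuple[MatchCounts, list[bool]]:
    """Greedy score-ordered matching within one class (and one image set:
    detections only ever match ground truth with the same image_id).

    Returns the aggregate counts and a per-detection TP/FP label aligned with
    the *input* order of ``dets``.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    matched = [False] * len(gts)
    labels = [False] * len(dets)
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, -1.0
        for j, gt in enumerate(gts):
            if matched[j] or gt.image_id != det.image_id:
                continue
            v = _pair_iou(det, gt, kind)
            if v >= iou_thresh and v > 0 and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            labels[i] = True
    counts = MatchCounts(
        tp=sum(labels), fp=len(dets) - sum(labels), fn=len(gts) - sum(matched)
    )
    return counts, labels


def precision_recall_f1(c: MatchCounts) -> tuple[float, float, float]:
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def pr_curve(dets: Sequence[Detection], gts: Sequence[Detection],
             iou_thresh: float = 0.5, kind: str = "box", class_id: int = 0) -> PRCurve:
    """Cumulative precision/recall over detections sorted by descending score."""
    _, labels = match(dets, gts, iou_thresh, kind)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    tp_sorted = np.array([labels[i] for i in order], dtype=np.float64)
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(1.0 - tp_sorted)
    n_gt = len(gts)
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-300)
    recall = cum_tp / n_gt if n_gt else np.zeros_like(cum_tp)
    return PRCurve(precision=precision, recall=recall, class_id=class_id)


def average_precision(curve: PRCurve, n_gt: Optional[int] = None) -> float:
    """Area under the all-point precision envelope as a function of recall."""
    if curve.recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[1.0], curve.precision])
    # envelope: precision at recall r_i = max precision at recall >= r_i
    env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * env[1:]))


def mean_ap(per_class_ap: Sequence[float]) -> float:
    aps = [a for a in per_class_ap if a is not None]
    if not aps:
        raise ValueError("no class has a defined AP")
    return float(np.mean(aps))


def ap_over_range(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    thresholds: Iterable[float],
    kind: str = "box",
) -> float:
    """AP averaged over an IoU-threshold range (single class)."""
    aps = [average_precision(pr_curve(dets, gts, t, kind)) for t in thresholds]
    return float(np.mean(aps))


def miou(
    pred_regions: dict[int, np.ndarray],
    gt_regions: dict[int, np.ndarray],
) -> float:
    """Mean over categories of pooled-pixel IoU.

    ``pred_regions`` / ``gt_regions`` map class id -> boolean pixel array
    (any shape, but matching per class; pool over images by stacking or
    concatenating beforehand).  Classes absent from both sides are excluded
    from the mean and logged.
    """
    classes = sorted(set(pred_regions) | set(gt_regions))
    ious = []
    for c in classes:
        p = pred_regions.get(c)
        g = gt_regions.get(c)
        if p is None and g is None:
            continue
        if p is None or not np.any(p):
            if g is None or not np.any(g):
                logger.info("class %d empty in both prediction and ground truth; excluded", c)
                continue
            ious.append(0.0)
            continue
        if g is None or not np.any(g):
            ious.append(0.0)
            continue
        ious.append(mask_iou(p, g))
    if not ious:
        raise ValueError("no class present in prediction or ground truth")
    return float(np.mean(ious))


def max_f1_threshold(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_thresh: float = 0.5,
    kind: str = "box",
) -> tuple[float, float]:
    """Sweep the distinct detection scores as candidate confidence thresholds
    and return (threshold, F1) at the maximum; ties favor the lowest
    threshold (higher recall)."""
    if not dets:
        raise ValueError("need at least one detection")
    best_t, best_f1 = None, -1.0
    for t in sorted({d.score for d in dets}):
        kept = [d for d in dets if d.score >= t]
        counts, _ = match(kept, gts, iou_thresh, kind)
        _, _, f1 = precision_recall_f1(counts)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return float(best_t), float(best_f1)


def filtered_miou_report(
    per_image_miou: Sequence[float], floor: float = 0.75
) -> tuple[Optional[float], int]:
    """Mean over images whose mIoU exceeds ``floor``; the excluded count is
    reported alongside.  All-excluded -> (None, n)."""
    if not 0.0 <= floor <= 1.0:
        raise ValueError("floor must lie in [0, 1]")
    kept = [v for v in per_image_miou if v > floor]
    excluded = len(per_image_miou) - len(kept)
    if not kept:
        return None, excluded
    return float(np.mean(kept)), excluded


def evaluate(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_thresh: float = 0.5,
    kind: str = "box",
    ap_range: Optional[Sequence[float]] = None,
) -> MetricsReport:
    """Full report at the max-F1 operating point, pooled over classes.

    ``ap_range`` defaults to 0.50..0.90 step 0.05 (switchable to the 0.50..0.95
    COCO convention by passing it explicitly).
    """
    if ap_range is None:
        ap_range = np.arange(0.50, 0.901, 0.05)
    classes = sorted({g.class_id for g in gts})
    per_class_ap, per_class_ap_range = [], []
    for c in classes:
        dc = [d for d in dets if d.class_id == c]
        gc = [g for g in gts if g.class_id == c]
        if not gc:
            logger.info("class %d has no ground truth; AP undefined, excluded", c)
            per_class_ap.append(None)
            per_class_ap_range.append(None)
            continue
        per_class_ap.append(average_precision(pr_curve(dc, gc, iou_thresh, kind)))
        per_class_ap_range.append(ap_over_range(dc, gc, ap_range, kind))
    if dets:
        thresh, _ = max_f1_threshold(dets, gts, iou_thresh, kind)
        kept = [d for d in dets if d.score >= thresh]
    else:
        thresh, kept = 1.0, []
    counts, _ = match(kept, gts, iou_thresh, kind)
    p, r, f1 = precision_recall_f1(counts)
    if kind == "mask" and gts and gts[0].mask is not None:
        shape = gts[0].mask.mask.shape
        image_ids = sorted({g.image_id for g in gts} | {d.image_id for d in kept})
        pred_px = {c: [] for c in classes}
        gt_px = {c: [] for c in classes}
        for iid in image_ids:
            for c in classes:
                pm = np.zeros(shape, bool)
                for d in kept:
                    if d.image_id == iid and d.class_id == c and d.mask is not None:
                        pm |= d.mask.mask
                gm = np.zeros(shape, bool)
                for g in gts:
                    if g.image_id == iid and g.class_id == c and g.mask is not None:
                        gm |= g.mask.mask
                pred_px[c].append(pm)
                gt_px[c].append(gm)
        miou_val = miou(
            {c: np.stack(v) for c, v in pred_px.items()},
            {c: np.stack(v) for c, v in gt_px.items()},
        )
    else:
        miou_val = float("nan")
    return MetricsReport(
        precision=p,
        recall=r,
        f1=f1,
        ap=mean_ap(per_class_ap),
        map50=mean_ap(per_class_ap),
        map_range=mean_ap(per_class_ap_range),
        miou=miou_val,
        n_classes=len([a for a in per_class_ap if a is not None]),
        operating_threshold=thresh,
    )
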