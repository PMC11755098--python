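"""Deterministic plantation-like scene generator and test-double backends.

Scenes emulate the geometric/statistical structure of UAV canopy imagery
rather than its appearance: smooth blob instances (randomized
ellipse-harmonic boundaries) stand in for crop canopies, thin strips
spanning the frame emulate transport-cable occluders, small background
blobs emulate weed clutter that must never count as foreground, and a
per-scene radius multiplier drawn from {1.0, 2.4} emulates the target-size
change between 12 m and 5 m flight altitudes (ratio 12/5).

All randomness flows from one seed through ``numpy`` seed-sequence spawning
with fixed keys per sub-stream (layout / boundary / occluder / clutter /
texture), so e.g. an occluder-free re-render of the same seed has an
identical layout.

The oracle segmenter and mock detector implement the backend contracts of
:mod:`alsseg.annotation_loop` on top of known ground truth; the detector's
accuracy follows a learning-curve schedule keyed by labeled-set size, which
reproduces the qualitative annotate-more/segment-better trend the loop is
designed to exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .annotation_loop import (
    DetectorBackend,
    PromptSet,
    SegmenterBackend,
    minimum_bounding_box,
)
from .geometry import BBox, InstanceMask, box_iou

__all__ = [
    "SceneConfig",
    "OracleConfig",
    "GenerationError",
    "generate_scene",
    "generate_dataset",
    "perturb_box",
    "sample_point_prompts",
    "oracle_segmenter",
    "mock_detector",
    "OracleSegmenter",
    "MockDetector",
    "DEFAULT_LEARNING_CURVE",
]


class GenerationError(RuntimeError):
    """Instance packing for a scene configuration is infeasible."""


@dataclass(frozen=True)
class SceneConfig:
    image_size: tuple[int, int] = (192, 192)  # (H, W)
    n_instances: int = 4
    radius_range: tuple[float, float] = (8.0, 13.0)
    altitude_scales: tuple[float, ...] = (1.0, 2.4)  # 12 m vs 5 m flight altitude
    occluder_strips: int = 1
    occluder_width: tuple[float, float] = (3.0, 8.0)
    clutter_density: float = 0.1
    texture_noise: float = 0.05
    seed: int = 0


# learning-curve schedule: (min labeled images, miss rate, corner jitter px)
DEFAULT_LEARNING_CURVE: tuple[tuple[int, float, float], ...] = (
    (0, 0.5, 4.0),
    (8, 0.25, 2.0),
    (16, 0.1, 1.0),
    (24, 0.0, 0.5),
)


@dataclass(frozen=True)
class OracleConfig:
    boundary_noise: float = 0.0  # px, segmenter mask-edge noise
    miss_rate: float = 0.0
    fp_rate: float = 0.0
    jitter: float = 0.0  # px, detector corner noise
    learning_curve: Optional[tuple[tuple[int, float, float], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0 or not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Scene generation


def _blob_mask(shape, cx, cy, radius, rng) -> np.ndarray:
    """Rasterize a smooth blob: r(theta) with a few random low-order
    harmonics on top of the base radius."""
    theta = np.linspace(0, 2 * math.pi, 96, endpoint=False)
    r = np.full_like(theta, 1.0)
    for k in range(2, 6):
        amp = rng.uniform(0.0, 0.12) / math.sqrt(k - 1)
        phase = rng.uniform(0, 2 * math.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.4, None) * radius
    ys = cy + r * np.sin(theta)
    xs = cx + r * np.cos(theta)
    rr, cc = draw_polygon(ys, xs, shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _strip_mask(shape, rng, width_range) -> np.ndarray:
    """A straight strip of random orientation/offset spanning the frame."""
    h, w = shape
    angle = rng.uniform(0, math.pi)
    nx, ny = math.sin(angle), -math.cos(angle)  # unit normal
    cx, cy = rng.uniform(0.2, 0.8) * w, rng.uniform(0.2, 0.8) * h
    width = rng.uniform(*width_range)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.abs((xx - cx) * nx + (yy - cy) * ny)
    return dist < width / 2.0


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, list[InstanceMask], list[BBox]]:
    """Render one scene; same config (incl. seed) -> byte-identical output.

    Returns (image float32 HxWx3 in [0,1], instance masks, their minimum
    bounding boxes).
    """
    h, w = cfg.image_size
    shape = (h, w)
    ss = np.random.SeedSequence(cfg.seed)
    layout_rng, boundary_rng, occ_rng, clutter_rng, tex_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    scale = float(layout_rng.choice(np.asarray(cfg.altitude_scales)))
    centers: list[tuple[float, float, float]] = []  # (cx, cy, radius)
    for _ in range(cfg.n_instances):
        placed = False
        for _try in range(3000):
            radius = layout_rng.uniform(*cfg.radius_range) * scale
            margin = radius * 1.25
            if 2 * margin >= min(h, w):
                continue
            cx = layout_rng.uniform(margin, w - margin)
            cy = layout_rng.uniform(margin, h - margin)
            if all(
                math.hypot(cx - ox, cy - oy) >= 0.75 * (radius + orad)
                for ox, oy, orad in centers
            ):
                centers.append((cx, cy, radius))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place {cfg.n_instances} instances of radius "
                f"{cfg.radius_range} x{scale} in a {h}x{w} frame"
            )
    masks = []
    occupied = np.zeros(shape, bool)
    for cx, cy, radius in centers:
        m = _blob_mask(shape, cx, cy, radius, boundary_rng)
        m &= ~occupied  # later instances never steal earlier pixels
        occupied |= m
        masks.append(m)

    # image: soil-toned background, greener instance interiors, weed clutter
    image = np.empty((h, w, 3), np.float32)
    image[:] = (0.42, 0.36, 0.25)
    n_clutter = int(round(cfg.clutter_density * h * w / 900.0))
    for _ in range(n_clutter):
        ccx, ccy = clutter_rng.uniform(0, w), clutter_rng.uniform(0, h)
        cr = clutter_rng.uniform(1.5, 4.0)
        cm = _blob_mask(shape, ccx, ccy, cr, clutter_rng)
        cm &= ~occupied  # clutter never overwrites instances -> never foreground
        shade = clutter_rng.uniform(0.35, 0.55)
        image[cm] = (0.25, shade, 0.18)
    for i, m in enumerate(masks):
        g = 0.5 + 0.12 * ((i % 3) - 1)
        image[m] = (0.18, g, 0.2)

    # occluder strips: drawn over everything and carved out of the masks
    for _ in range(cfg.occluder_strips):
        strip = _strip_mask(shape, occ_rng, cfg.occluder_width)
        image[strip] = (0.55, 0.55, 0.55)
        for m in masks:
            m &= ~strip

    if cfg.texture_noise > 0:
        image += tex_rng.normal(0.0, cfg.texture_noise, size=image.shape).astype(np.float32)
        np.clip(image, 0.0, 1.0, out=image)

    out_masks, out_boxes = [], []
    for i, m in enumerate(masks):
        if not m.any():
            continue
        im = InstanceMask(m, instance_id=len(out_masks), class_id=0)
        out_masks.append(im)
        out_boxes.append(minimum_bounding_box(im))
    return image, out_masks, out_boxes


def generate_dataset(
    n_scenes: int, seed: int = 0, cfg: Optional[SceneConfig] = None
) -> dict[int, tuple[np.ndarray, list[InstanceMask], list[BBox]]]:
    """n scenes with per-scene seeds derived from (seed, index)."""
    base = cfg or SceneConfig()
    out = {}
    for i in range(n_scenes):
        scene_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        scfg = SceneConfig(
            image_size=base.image_size,
            n_instances=base.n_instances,
            radius_range=base.radius_range,
            altitude_scales=base.altitude_scales,
            occluder_strips=base.occluder_strips,
            occluder_width=base.occluder_width,
            clutter_density=base.clutter_density,
            texture_noise=base.texture_noise,
            seed=scene_seed,
        )
        out[i] = generate_scene(scfg)
    return out


# ---------------------------------------------------------------------------
# Prompt construction


def perturb_box(box: BBox, pct: float, bounds: Optional[tuple[int, int]] = None) -> BBox:
    """Enlarge a box by ``pct``: width and height each scaled by (1 + pct)
    about the center (continuous extents), then clipped to (W, H) bounds if
    given — the MBB+5%/+10%/+20% prompt variants."""
    if pct < 0:
        raise ValueError("pct must be >= 0")
    out = box.scale_about_center(1.0 + pct)
    if bounds is not None:
        out = out.clip(*bounds)
    return out


def sample_point_prompts(
    mask: InstanceMask, n_pos: int, n_neg: int = 0, seed: int = 0
) -> PromptSet:
    """Reproducible positive points strictly inside the mask and negative
    points just outside it (within a dilated ring)."""
    if mask.is_empty:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    interior = ndimage.binary_erosion(mask.mask)
    pool = interior if interior.sum() >= n_pos else mask.mask
    ys, xs = np.nonzero(pool)
    if len(ys) < n_pos:
        raise ValueError(f"mask too small for {n_pos} positive points")
    idx = rng.choice(len(ys), size=n_pos, replace=False)
    positive = [(float(xs[i]), float(ys[i])) for i in idx]
    negative = []
    if n_neg:
        ring = ndimage.binary_dilation(mask.mask, iterations=10) & ~mask.mask
        ys, xs = np.nonzero(ring)
        if len(ys) < n_neg:
            raise ValueError(f"not enough background near the mask for {n_neg} points")
        idx = rng.choice(len(ys), size=n_neg, replace=False)
        negative = [(float(xs[i]), float(ys[i])) for i in idx]
    return PromptSet(positive=positive, negative=negative)


# ---------------------------------------------------------------------------
# Backends


def _perturb_boundary(mask: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter a mask's boundary by ~sigma pixels: threshold the signed
    distance transform shifted by a smooth random field."""
    if sigma <= 0:
        return mask.copy()
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside
    noise = ndimage.gaussian_filter(rng.normal(size=mask.shape), 4.0)
    noise /= max(noise.std(), 1e-9)
    return (signed + sigma * noise) > 0


class OracleSegmenter(SegmenterBackend):
    """Ground-truth-backed promptable segmenter.

    Box prompt: returns the mask of the instance whose bounding box best
    overlaps the prompt box (boundary-perturbed when configured); a box over
    background yields nothing.  Point prompts: the instance holding the
    majority of positive points, vetoed entirely if a negative point falls
    inside it.
    """

    def __init__(self, cfg: OracleConfig, truth: Mapping[int, Sequence[InstanceMask]]):
        self.cfg = cfg
        self.truth = truth
        self._boxes = {iid: [minimum_bounding_box(m) for m in ms] for iid, ms in truth.items()}
        self._calls = 0

    def _noisy(self, mask: InstanceMask, image_id: int) -> InstanceMask:
        self._calls += 1
        if self.cfg.boundary_noise <= 0:
            return InstanceMask(mask.mask.copy(), mask.instance_id, mask.class_id)
        rng = np.random.default_rng(
            np.random.SeedSequence((self.cfg.seed, image_id, self._calls))
        )
        noisy = _perturb_boundary(mask.mask, self.cfg.boundary_noise, rng)
        return InstanceMask(noisy, mask.instance_id, mask.class_id)

    def segment(self, image_id: int, image: np.ndarray, prompts: PromptSet) -> list[InstanceMask]:
        gt_masks = list(self.truth.get(image_id, []))
        gt_boxes = self._boxes.get(image_id, [])
        out: list[InstanceMask] = []
        if prompts.boxes:
            for b in prompts.boxes:
                best, best_iou = None, 0.0
                for m, gb in zip(gt_masks, gt_boxes):
                    v = box_iou(b, gb)
                    if v > best_iou:
                        best, best_iou = m, v
                if best is not None:
                    out.append(self._noisy(best, image_id))
            return out
        if prompts.positive:
            votes = np.zeros(len(gt_masks), int)
            for x, y in prompts.positive:
                for i, m in enumerate(gt_masks):
                    if m.mask[int(round(y)), int(round(x))]:
                        votes[i] += 1
            if not votes.any():
                return []
            pick = int(votes.argmax())
            for x, y in prompts.negative:
                if gt_masks[pick].mask[int(round(y)), int(round(x))]:
                    return []  # negative point vetoes the chosen instance
            return [self._noisy(gt_masks[pick], image_id)]
        return []


class MockDetector(DetectorBackend):
    """Ground-truth-backed detector whose error rates follow a learning
    curve: train() looks up (miss_rate, jitter) from the labeled-set size;
    predict() drops each true box with miss_rate, jitters the survivors'
    corners, and adds Poisson(fp_rate * n) spurious boxes."""

    def __init__(self, cfg: OracleConfig, truth_boxes: Mapping[int, Sequence[BBox]]):
        self.cfg = cfg
        self.truth_boxes = truth_boxes
        self._epoch = 0
        self._miss = cfg.miss_rate
        self._jitter = cfg.jitter
        self._trained = False

    @property
    def is_trained(self) -> bool:
        return self._trained

    @property
    def stage(self) -> tuple[float, float]:
        return self._miss, self._jitter

    def train(self, labeled) -> None:
        self._epoch += 1
        self._trained = True
        n = len(labeled)
        if self.cfg.learning_curve:
            for min_n, miss, jitter in sorted(self.cfg.learning_curve):
                if n >= min_n:
                    self._miss, self._jitter = miss, jitter
        # without a curve the configured rates are static

    def predict(self, image_id: int, image: np.ndarray) -> list[BBox]:
        if not self._trained:
            raise RuntimeError("mock detector: predict before train")
        h, w = image.shape[:2]
        rng = np.random.default_rng(
            np.random.SeedSequence((self.cfg.seed, self._epoch, image_id))
        )
        out: list[BBox] = []
        gt = list(self.truth_boxes.get(image_id, []))
        for b in gt:
            if rng.random() < self._miss:
                continue
            j = rng.normal(0.0, self._jitter, size=4) if self._jitter > 0 else np.zeros(4)
            xmin, ymin = b.xmin + j[0], b.ymin + j[1]
            xmax, ymax = max(b.xmax + j[2], xmin), max(b.ymax + j[3], ymin)
            out.append(
                BBox(xmin, ymin, xmax, ymax, score=float(rng.uniform(0.6, 1.0)),
                     class_id=b.class_id).clip(w, h)
            )
        n_fp = rng.poisson(self.cfg.fp_rate * max(len(gt), 1)) if self.cfg.fp_rate > 0 else 0
        for _ in range(n_fp):
            bw, bh = rng.uniform(5, w / 3), rng.uniform(5, h / 3)
            x0 = rng.uniform(0, w - bw)
            y0 = rng.uniform(0, h - bh)
            out.append(
                BBox(x0, y0, x0 + bw, y0 + bh, score=float(rng.uniform(0.3, 0.7))).clip(w, h)
            )
        return out


def oracle_segmenter(cfg: OracleConfig, truth: Mapping[int, Sequence[InstanceMask]]) -> OracleSegmenter:
    return OracleSegmenter(cfg, truth)


def mock_detector(cfg: OracleConfig, truth_boxes: Mapping[int, Sequence[BBox]]) -> MockDetector:
    return MockDetector(cfg, truth_boxes)
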