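"""Declarative network graph: assembly, inference, and instance decoding.

The model is a YOLACT-style single-stage instance segmenter: a lightweight
backbone (CBS / ALSS / SPPF), an FPN-style neck with one MSCA attention
block, and a head that emits — in parallel — per-cell box distributions
(DFL bins), class logits and mask coefficients at three strides (8/16/32),
plus a bank of k shared prototype maps at quarter resolution.  An instance
mask is the sigmoid of the coefficient-weighted sum of prototypes, cropped
to the instance box and thresholded at 0.5.

The default graph is shipped as ``alss_yolo_seg.yaml`` next to this module;
:meth:`NetworkSpec.default` loads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from . import blocks as B
from .blocks import ConfigError, ShapeError, sigmoid, silu
from .geometry import BBox, InstanceMask, box_iou

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "LevelOutput",
    "HeadOutput",
    "PrototypeBank",
    "Instance",
    "Network",
    "build_network",
    "forward",
    "decode_boxes",
    "assemble_mask",
    "postprocess",
    "summarize",
    "letterbox",
]

LAYER_KINDS = ("input", "conv", "alss", "sppf", "upsample", "concat", "msca", "segment")


@dataclass(frozen=True)
class LayerSpec:
    index: int
    kind: str
    sources: Optional[tuple[int, ...]] = None  # default: (index - 1,)
    out_channels: Optional[int] = None
    kernel: int = 3
    stride: int = 1
    split_fraction: float = 0.5
    bottleneck_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ConfigError(f"layer {self.index}: unknown kind {self.kind!r}")

    @property
    def src(self) -> tuple[int, ...]:
        return self.sources if self.sources is not None else (self.index - 1,)


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    input_size: tuple[int, int, int] = (640, 640, 3)  # H, W, C
    num_classes: int = 1
    reg_max: int = 24
    num_prototypes: int = 32
    name: str = "network"

    def __post_init__(self) -> None:
        n_seg = sum(1 for l in self.layers if l.kind == "segment")
        if n_seg != 1:
            raise ConfigError(f"spec must contain exactly one segment layer, found {n_seg}")
        for l in self.layers:
            for s in l.src:
                if l.kind != "input" and s >= l.index:
                    raise ConfigError(f"layer {l.index}: source {s} does not precede it")

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        layers = []
        for row in d["layers"]:
            row = dict(row)
            if "sources" in row and row["sources"] is not None:
                row["sources"] = tuple(row["sources"])
            layers.append(LayerSpec(**row))
        return cls(
            layers=layers,
            input_size=tuple(d.get("input_size", (640, 640, 3))),
            num_classes=int(d.get("num_classes", 1)),
            reg_max=int(d.get("reg_max", 24)),
            num_prototypes=int(d.get("num_prototypes", 32)),
            name=d.get("name", "network"),
        )

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "NetworkSpec":
        text = resources.files("alsseg").joinpath("alss_yolo_seg.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class LevelOutput:
    box_dist: np.ndarray  # (H, W, 4*reg_max) raw logits
    cls_logits: np.ndarray  # (H, W, num_classes)
    coefficients: np.ndarray  # (H, W, k), tanh-squashed to [-1, 1]
    stride: int


@dataclass
class HeadOutput:
    levels: list[LevelOutput]


@dataclass
class PrototypeBank:
    maps: np.ndarray  # (Hp, Wp, k)

    @property
    def k(self) -> int:
        return self.maps.shape[2]


@dataclass
class Instance:
    bbox: BBox
    score: float
    class_id: int
    mask: Optional[InstanceMask] = None


# ---------------------------------------------------------------------------
# Head


class SegmentHead:
    """Decoupled detection branches (box-distribution, class, coefficient) per
    level plus a prototype branch fed by the highest-resolution level."""

    def __init__(self, level_channels: Sequence[int], num_classes: int, reg_max: int,
                 k: int, rng: np.random.Generator):
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.k = k
        self.box_branches = []
        self.cls_branches = []
        self.coef_branches = []
        hb = 4 * reg_max  # box-branch hidden width
        hc = level_channels[0]  # class/coefficient hidden width
        for c in level_channels:
            self.box_branches.append([
                B.CBS(c, hb, 3, rng=rng),
                B.CBS(hb, hb, 3, rng=rng),
                B.Conv(B.ConvSpec(hb, 4 * reg_max, 1, has_bias=True, has_bn=False, activation="none"), rng),
            ])
            self.cls_branches.append([
                B.CBS(c, hc, 3, rng=rng),
                B.CBS(hc, hc, 3, rng=rng),
                B.Conv(B.ConvSpec(hc, num_classes, 1, has_bias=True, has_bn=False, activation="none"), rng),
            ])
            self.coef_branches.append([
                B.CBS(c, hc, 3, rng=rng),
                B.Conv(B.ConvSpec(hc, k, 1, has_bias=True, has_bn=False, activation="none"), rng),
            ])
        c0 = level_channels[0]
        self.proto_convs = [
            B.CBS(c0, c0, 3, rng=rng),  # before 2x upsample
            B.CBS(c0, c0, 3, rng=rng),
            B.Conv(B.ConvSpec(c0, k, 1, has_bias=True, has_bn=False, activation="none"), rng),
        ]

    @staticmethod
    def _run(branch, x):
        for layer in branch:
            x = layer(x)
        return x

    def forward(self, feats: Sequence[np.ndarray], strides: Sequence[int]) -> tuple[HeadOutput, PrototypeBank]:
        levels = []
        for i, (x, s) in enumerate(zip(feats, strides)):
            levels.append(
                LevelOutput(
                    box_dist=self._run(self.box_branches[i], x),
                    cls_logits=self._run(self.cls_branches[i], x),
                    coefficients=np.tanh(self._run(self.coef_branches[i], x)),
                    stride=s,
                )
            )
        p = self.proto_convs[0](feats[0])
        p = B._upsample_nearest(p, 2)
        p = self.proto_convs[1](p)
        p = self.proto_convs[2](p)
        return HeadOutput(levels), PrototypeBank(p)

    def param_count(self) -> int:
        total = 0
        for branches in (self.box_branches, self.cls_branches, self.coef_branches):
            for branch in branches:
                total += sum(l.param_count() for l in branch)
        total += sum(l.param_count() for l in self.proto_convs)
        return total


# ---------------------------------------------------------------------------
# Network


class Network:
    """A runnable layer graph with per-layer parameter/MAC reports."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w, c = spec.input_size
        self.shapes: dict[int, tuple[int, int, int]] = {}
        self.blocks: dict[int, object] = {}
        self.reports: list[B.BlockParamReport] = []
        seg_layer = None
        for l in spec.layers:
            if l.kind == "input":
                self.shapes[l.index] = (h, w, c)
                self.reports.append(B.BlockParamReport("Input", 0, 0))
                continue
            src_shapes = []
            for s in l.src:
                if s not in self.shapes:
                    raise ConfigError(f"layer {l.index}: source {s} not built")
                src_shapes.append(self.shapes[s])
            sh, sw, sc = src_shapes[0]
            if l.kind == "conv":
                spec_c = B.ConvSpec(sc, l.out_channels, l.kernel, l.stride)
                blk = B.Conv(spec_c, rng)
                oh = (sh + 2 * spec_c.pad - l.kernel) // l.stride + 1
                ow = (sw + 2 * spec_c.pad - l.kernel) // l.stride + 1
                shape = (oh, ow, l.out_channels)
            elif l.kind == "alss":
                blk = B.ALSS(
                    B.ALSSConfig(sc, l.out_channels, l.stride, l.split_fraction, l.bottleneck_ratio),
                    rng,
                )
                shape = (sh // l.stride, sw // l.stride, l.out_channels)
            elif l.kind == "sppf":
                if l.out_channels not in (None, sc):
                    raise ConfigError(f"layer {l.index}: SPPF preserves channel count")
                blk = B.SPPF(sc, rng)
                shape = (sh, sw, sc)
            elif l.kind == "upsample":
                blk = None
                shape = (sh * 2, sw * 2, sc)
            elif l.kind == "concat":
                total_c = sum(s[2] for s in src_shapes)
                if any(s[:2] != src_shapes[0][:2] for s in src_shapes):
                    raise ConfigError(f"layer {l.index}: concat sources differ in spatial size")
                if l.out_channels is not None and l.out_channels != total_c:
                    raise ConfigError(
                        f"layer {l.index}: concat channels {total_c} != declared {l.out_channels}"
                    )
                blk = None
                shape = (sh, sw, total_c)
            elif l.kind == "msca":
                blk = B.MSCA(B.MSCAConfig(sc), rng)
                shape = (sh, sw, sc)
            elif l.kind == "segment":
                seg_layer = l
                level_channels = [self.shapes[s][2] for s in l.src]
                strides = [spec.input_size[0] // self.shapes[s][0] for s in l.src]
                blk = SegmentHead(level_channels, spec.num_classes, spec.reg_max,
                                  spec.num_prototypes, rng)
                self._head_strides = strides
                shape = src_shapes[0]  # placeholder; head output is structured
            else:  # pragma: no cover
                raise ConfigError(f"layer {l.index}: unhandled kind {l.kind}")
            self.shapes[l.index] = shape
            self.blocks[l.index] = blk
            params = blk.param_count() if blk is not None and hasattr(blk, "param_count") else 0
            macs = 0
            if blk is not None and hasattr(blk, "macs") and l.kind != "segment":
                macs = blk.macs(shape[0], shape[1])
            self.reports.append(B.BlockParamReport(l.kind.capitalize() if l.kind != "msca" else "MSCA", params, macs))
        self.segment_spec = seg_layer

    @property
    def total_params(self) -> int:
        return sum(r.learnable_params for r in self.reports)

    def layer_params(self, index: int) -> int:
        return self.reports[index].learnable_params

    def forward(self, image: np.ndarray) -> tuple[HeadOutput, PrototypeBank]:
        h, w, c = self.spec.input_size
        if image.shape != (h, w, c):
            raise ShapeError(f"expected input {(h, w, c)}, got {image.shape}")
        acts: dict[int, np.ndarray] = {}
        out = None
        for l in self.spec.layers:
            if l.kind == "input":
                acts[l.index] = np.asarray(image, dtype=np.float32)
                continue
            srcs = [acts[s] for s in l.src]
            blk = self.blocks[l.index]
            if l.kind == "upsample":
                y = B._upsample_nearest(srcs[0], 2)
            elif l.kind == "concat":
                y = np.concatenate(srcs, axis=2)
            elif l.kind == "segment":
                out = blk.forward(srcs, self._head_strides)
                y = srcs[0]
            else:
                y = blk(srcs[0])
            acts[l.index] = y
        assert out is not None
        return out

    __call__ = forward


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    return Network(spec, seed)


def forward(network: Network, image: np.ndarray) -> tuple[HeadOutput, PrototypeBank]:
    return network.forward(image)


# ---------------------------------------------------------------------------
# Decoding


def decode_boxes(box_dist: np.ndarray, reg_max: int, stride: int) -> np.ndarray:
    """Decode DFL side distances: each of the four sides is the expectation of
    a softmax distribution over ``reg_max`` bins, scaled by the level stride.

    ``box_dist`` is (..., 4*reg_max); returns (..., 4) distances
    (left, top, right, bottom), each in [0, (reg_max-1)*stride].
    """
    shape = box_dist.shape[:-1]
    logits = box_dist.reshape(*shape, 4, reg_max)
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=-1, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float64)
    return (p * bins).sum(axis=-1) * stride


def assemble_mask(
    coefficients: np.ndarray,
    prototypes: PrototypeBank,
    box: BBox,
    image_size: tuple[int, int],
) -> InstanceMask:
    """Combine prototypes with one instance's coefficient vector.

    mask = threshold(sigmoid(sum_j c_j P_j) > 0.5) cropped to the box
    (YOLACT convention: crop before thresholding), then upsampled to image
    resolution by nearest neighbour.  The strict > breaks the all-zero
    coefficient tie toward background.
    """
    coefficients = np.asarray(coefficients, dtype=np.float32)
    maps = prototypes.maps
    if coefficients.shape[0] != maps.shape[2]:
        raise ShapeError("coefficient length != number of prototypes")
    logits = maps @ coefficients
    prob = sigmoid(logits)
    hp, wp = prob.shape
    ih, iw = image_size
    sy, sx = hp / ih, wp / iw
    x0 = max(0, int(math.floor(box.xmin * sx)))
    y0 = max(0, int(math.floor(box.ymin * sy)))
    x1 = min(wp - 1, int(math.ceil(box.xmax * sx)))
    y1 = min(hp - 1, int(math.ceil(box.ymax * sy)))
    cropped = np.zeros_like(prob)
    cropped[y0 : y1 + 1, x0 : x1 + 1] = prob[y0 : y1 + 1, x0 : x1 + 1]
    small = cropped > 0.5
    fy, fx = ih // hp, iw // wp
    if fy * hp != ih or fx * wp != iw:
        raise ShapeError("image size must be an integer multiple of prototype size")
    full = small.repeat(fy, axis=0).repeat(fx, axis=1)
    return InstanceMask(full)


def postprocess(
    head: HeadOutput,
    prototypes: PrototypeBank,
    conf_thresh: float = 0.3,
    nms_iou: float = 0.5,
    image_size: Optional[tuple[int, int]] = None,
) -> list[Instance]:
    """Score filtering, per-class greedy NMS, and mask assembly.

    Deterministic: candidates are ordered by (score desc, flattened cell index
    asc) before suppression, so the output does not depend on input order.
    """
    if not 0.0 <= conf_thresh <= 1.0 or not 0.0 <= nms_iou <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    if image_size is None:
        lvl0 = head.levels[0]
        image_size = (lvl0.box_dist.shape[0] * lvl0.stride, lvl0.box_dist.shape[1] * lvl0.stride)
    ih, iw = image_size
    candidates = []  # (score, order, class_id, BBox, coefs)
    order = 0
    reg_max = head.levels[0].box_dist.shape[-1] // 4
    for lvl in head.levels:
        scores = sigmoid(lvl.cls_logits)
        dists = decode_boxes(lvl.box_dist, reg_max, lvl.stride)
        hh, ww, nc = scores.shape
        ys, xs, cs = np.nonzero(scores > conf_thresh)
        for y, x, c in zip(ys, xs, cs):
            cx = (x + 0.5) * lvl.stride
            cy = (y + 0.5) * lvl.stride
            left, top, right, bottom = dists[y, x]
            box = BBox(
                xmin=cx - left, ymin=cy - top, xmax=cx + right, ymax=cy + bottom,
                score=float(scores[y, x, c]), class_id=int(c),
            ).clip(iw, ih)
            candidates.append((float(scores[y, x, c]), order, int(c), box, lvl.coefficients[y, x]))
            order += 1
    candidates.sort(key=lambda t: (-t[0], t[1]))
    survivors: list[tuple[float, int, BBox, np.ndarray]] = []
    for score, _, cls, box, coefs in candidates:
        if any(c == cls and box_iou(box, b) > nms_iou for _, c, b, _ in survivors):
            continue
        survivors.append((score, cls, box, coefs))
    instances = []
    for score, cls, box, coefs in survivors:
        mask = assemble_mask(coefs, prototypes, box, image_size)
        instances.append(Instance(bbox=box, score=score, class_id=cls, mask=mask))
    return instances


# ---------------------------------------------------------------------------
# Reporting & preprocessing


def summarize(network: Network) -> str:
    """Layer-by-layer table: index, module, output shape, params, GFLOPs
    (2 x MACs convention), ending in a Total row."""
    lines = [f"{'Number':>6}  {'Module':<10} {'Output':<14} {'Params':>10} {'GFLOPs':>8}"]
    total_p = 0
    total_g = 0.0
    for l, rep in zip(network.spec.layers, network.reports):
        h, w, c = network.shapes[l.index]
        shape = "-" if l.kind == "segment" else f"{c}x{h}x{w}"
        gflops = 2.0 * rep.macs / 1e9
        total_p += rep.learnable_params
        total_g += gflops
        params = "-" if l.kind == "input" else str(rep.learnable_params)
        lines.append(f"{l.index:>6}  {rep.block_name:<10} {shape:<14} {params:>10} {gflops:>8.2f}")
    lines.append(f"{'-':>6}  {'Total':<10} {'-':<14} {total_p:>10} {total_g:>8.2f}")
    return "\n".join(lines)


def letterbox(
    image: np.ndarray,
    size: tuple[int, int] = (640, 640),
    pad_value: float = 114.0 / 255.0,
) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Aspect-preserving resize onto a square canvas, top-left anchored.

    Returns (canvas, scale, (pad_x, pad_y)); with top-left anchoring the pads
    are zero but are returned for coordinate back-mapping symmetry.
    """
    from skimage.transform import resize as _resize

    th, tw = size
    h, w = image.shape[:2]
    scale = min(th / h, tw / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = _resize(image, (nh, nw), order=1, anti_aliasing=True, preserve_range=True)
    canvas = np.full((th, tw) + image.shape[2:], pad_value, dtype=np.float32)
    canvas[:nh, :nw] = resized
    return canvas, scale, (0, 0)
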