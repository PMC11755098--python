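"""Computational blocks of the lightweight segmentation backbone.

All blocks operate on channels-last feature maps (H, W, C) of float32 and are
pure NumPy inference implementations: convolution by im2col + matmul,
max-pooling via :func:`scipy.ndimage.maximum_filter`, batch-norm in frozen
(inference) mode.  Each block knows its own learnable-parameter count in
closed form, which is what the layer-by-layer model summary reports.

Conventions that the parameter accounting relies on:

* A CBS block is convolution *without* bias, batch normalization with two
  learnable parameters per channel (scale and shift), then SiLU.
* The multi-scale channel attention (MSCA) block uses bias-free convolutions
  throughout, no batch norm, and no activation after its channel-reduction
  or depthwise convolutions; the logistic squashing is applied only to the
  final channel-expansion output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ConvSpec",
    "ALSSConfig",
    "MSCAConfig",
    "BlockParamReport",
    "ConfigError",
    "ShapeError",
    "count_params",
    "msca_param_count",
    "channel_shuffle",
    "conv2d",
    "adaptive_avg_pool",
    "silu",
    "sigmoid",
    "CBS",
    "Conv",
    "SPPF",
    "ALSS",
    "MSCA",
]


class ConfigError(ValueError):
    """A block configuration violates its structural constraints."""


class ShapeError(ValueError):
    """An input tensor does not match the block's expected shape."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(x: np.ndarray) -> np.ndarray:
    return x * sigmoid(x)


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class ConvSpec:
    """Declarative convolution configuration.

    ``padding=None`` means "same" padding (kernel-1)//2; pass 0 explicitly
    for a valid convolution.
    """

    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    padding: Optional[int] = None
    depthwise: bool = False
    has_bias: bool = False
    has_bn: bool = True
    activation: str = "silu"

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("channel counts must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigError("kernel must be an odd integer >= 1")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.depthwise and self.in_channels != self.out_channels:
            raise ConfigError("depthwise convolution requires in_channels == out_channels")
        if self.activation not in ("silu", "none"):
            raise ConfigError(f"unknown activation {self.activation!r}")

    @property
    def pad(self) -> int:
        return (self.kernel - 1) // 2 if self.padding is None else self.padding

    @property
    def groups(self) -> int:
        return self.in_channels if self.depthwise else 1


def count_params(spec: ConvSpec) -> int:
    """Learnable parameters of one convolution under the declared convention:
    k^2 * Cin/groups * Cout weights, plus Cout bias terms if present, plus
    2*Cout batch-norm terms if present."""
    weights = spec.kernel**2 * (spec.in_channels // spec.groups) * spec.out_channels
    total = weights
    if spec.has_bias:
        total += spec.out_channels
    if spec.has_bn:
        total += 2 * spec.out_channels
    return total


@dataclass(frozen=True)
class ALSSConfig:
    """Adaptive lightweight split-and-shuffle block configuration.

    The input is split along channels into a shortcut path (kept cheap) and a
    main path routed through a 1x1-reduce / 3x3 / 1x1-expand bottleneck; the
    stride is applied in the 3x3 stage (and by a depthwise 3x3 on the shortcut
    when stride=2).  The concatenated result is channel-shuffled.
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    split_fraction: float = 0.5
    bottleneck_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ConfigError("ALSS stride must be 1 or 2")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.shortcut_channels < 1 or self.main_in_channels < 1:
            raise ConfigError("channel split produced an empty path")
        if self.main_out_channels < 1:
            raise ConfigError("out_channels leaves no room for the main path")

    @property
    def shortcut_channels(self) -> int:
        # capped at half the output width so channel-reducing layers
        # (out < in) still leave room for the main path
        want = int(round(self.in_channels * self.split_fraction))
        return max(1, min(want, self.out_channels // 2))

    @property
    def main_in_channels(self) -> int:
        return self.in_channels - self.shortcut_channels

    @property
    def main_out_channels(self) -> int:
        return self.out_channels - self.shortcut_channels

    @property
    def bottleneck_channels(self) -> int:
        return max(1, int(round(self.main_out_channels * self.bottleneck_ratio)))


@dataclass(frozen=True)
class MSCAConfig:
    """Multi-scale channel attention configuration.

    ``reduced`` is the compressed width r = max(1, floor(alpha * C)); the four
    pooling branches use target sizes (1, 3, 3, 5) with matching depthwise
    kernels so each branch collapses to a 1x1 descriptor.
    """

    channels: int
    alpha: float = 1.0 / 32.0
    pool_sizes: tuple[int, ...] = (1, 3, 3, 5)

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ConfigError("channels must be >= 1")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")

    @property
    def reduced(self) -> int:
        return max(1, int(math.floor(self.alpha * self.channels)))

    # each branch's depthwise kernel equals its pooled size
    @property
    def dw_kernels(self) -> tuple[int, ...]:
        return self.pool_sizes


def msca_param_count(cfg: MSCAConfig) -> int:
    """Closed-form learnable parameter count of the attention block:
    9*C*r (3x3 reduction) + r*sum(k^2) (depthwise branches) + 4r*C (1x1
    expansion); no biases or batch norm anywhere."""
    r = cfg.reduced
    reduction = 9 * cfg.channels * r
    branches = r * sum(k * k for k in cfg.dw_kernels)
    expansion = len(cfg.pool_sizes) * r * cfg.channels
    return reduction + branches + expansion


@dataclass
class BlockParamReport:
    block_name: str
    learnable_params: int
    macs: int = 0


# ---------------------------------------------------------------------------
# Primitive ops


def conv2d(
    x: np.ndarray,
    weight: np.ndarray,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
    bias: Optional[np.ndarray] = None,
) -> np.ndarray:
    """2-D cross-correlation on a channels-last map.

    ``x`` is (H, W, Cin); ``weight`` is (Cout, Cin/groups, k, k).  Uses a
    sliding-window view plus one matmul per group.
    """
    if x.ndim != 3:
        raise ShapeError("input must be (H, W, C)")
    cout, cin_g, kh, kw = weight.shape
    cin = x.shape[2]
    if cin != cin_g * groups:
        raise ShapeError(f"input has {cin} channels, weight expects {cin_g * groups}")
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    h, w, _ = x.shape
    if h < kh or w < kw:
        raise ShapeError("input smaller than kernel after padding")
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    win = win[::stride, ::stride]  # (Ho, Wo, Cin, kh, kw)
    ho, wo = win.shape[:2]
    out = np.empty((ho, wo, cout), dtype=np.float32)
    cpg = cin // groups  # channels per group
    opg = cout // groups
    for g in range(groups):
        cols = win[:, :, g * cpg : (g + 1) * cpg].reshape(ho * wo, cpg * kh * kw)
        wmat = weight[g * opg : (g + 1) * opg].reshape(opg, cpg * kh * kw)
        out[:, :, g * opg : (g + 1) * opg] = (cols @ wmat.T).reshape(ho, wo, opg)
    if bias is not None:
        out += bias
    return out


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Interleave channels: reshape C -> (groups, C/groups), transpose, and
    flatten.  A pure permutation of channel indices; pixel values untouched."""
    h, w, c = x.shape
    if c % groups != 0:
        raise ConfigError(f"{c} channels not divisible into {groups} groups")
    return x.reshape(h, w, groups, c // groups).swapaxes(2, 3).reshape(h, w, c)


def adaptive_avg_pool(x: np.ndarray, size: int) -> np.ndarray:
    """Adaptive average pooling to (size, size): output bin (i, j) averages the
    input region [floor(i*H/s), ceil((i+1)*H/s)) x [floor(j*W/s), ceil((j+1)*W/s))."""
    h, w, c = x.shape
    out = np.empty((size, size, c), dtype=np.float32)
    for i in range(size):
        r0, r1 = (i * h) // size, -(-((i + 1) * h) // size)
        for j in range(size):
            c0, c1 = (j * w) // size, -(-((j + 1) * w) // size)
            out[i, j] = x[r0:r1, c0:c1].mean(axis=(0, 1))
    return out


def max_pool(x: np.ndarray, kernel: int, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Max pooling with -inf padding (so pads never win)."""
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(0, 1))
    return np.ascontiguousarray(win[::stride, ::stride].max(axis=(3, 4)))


def _upsample_nearest(x: np.ndarray, factor: int = 2) -> np.ndarray:
    return x.repeat(factor, axis=0).repeat(factor, axis=1)


# ---------------------------------------------------------------------------
# Blocks with weights


class Conv:
    """Bare convolution layer (optionally with bias, BN, activation) holding
    its weights; the workhorse behind CBS and the bias-free attention convs."""

    def __init__(self, spec: ConvSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = spec.kernel**2 * (spec.in_channels // spec.groups)
        std = math.sqrt(2.0 / fan_in)
        self.weight = rng.normal(0.0, std, size=(
            spec.out_channels,
            spec.in_channels // spec.groups,
            spec.kernel,
            spec.kernel,
        )).astype(np.float32)
        self.bias = np.zeros(spec.out_channels, dtype=np.float32) if spec.has_bias else None
        if spec.has_bn:
            self.bn_gamma = np.ones(spec.out_channels, dtype=np.float32)
            self.bn_beta = np.zeros(spec.out_channels, dtype=np.float32)
            self.bn_mean = np.zeros(spec.out_channels, dtype=np.float32)
            self.bn_var = np.ones(spec.out_channels, dtype=np.float32)
            self.bn_eps = 1e-5

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        if x.shape[2] != s.in_channels:
            raise ShapeError(
                f"expected {s.in_channels} input channels, got {x.shape[2]}"
            )
        y = conv2d(x, self.weight, s.stride, s.pad, s.groups, self.bias)
        if s.has_bn:
            inv = self.bn_gamma / np.sqrt(self.bn_var + self.bn_eps)
            y = y * inv + (self.bn_beta - self.bn_mean * inv)
        if s.activation == "silu":
            y = silu(y)
        return y

    __call__ = forward

    def param_count(self) -> int:
        return count_params(self.spec)

    def macs(self, out_h: int, out_w: int) -> int:
        s = self.spec
        return s.kernel**2 * (s.in_channels // s.groups) * s.out_channels * out_h * out_w

    def zero_(self) -> None:
        """Zero all weights (and BN shift) — useful for degenerate-path checks."""
        self.weight[:] = 0
        if self.bias is not None:
            self.bias[:] = 0
        if self.spec.has_bn:
            self.bn_beta[:] = 0


def CBS(
    in_channels: int,
    out_channels: int,
    kernel: int = 1,
    stride: int = 1,
    padding: Optional[int] = None,
    depthwise: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Conv:
    """Convolution (no bias) + BatchNorm + SiLU."""
    spec = ConvSpec(
        in_channels,
        out_channels,
        kernel,
        stride,
        padding,
        depthwise=depthwise,
        has_bias=False,
        has_bn=True,
        activation="silu",
    )
    return Conv(spec, rng if rng is not None else np.random.default_rng(0))


def cbs_forward(x: np.ndarray, spec: ConvSpec, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One-shot CBS application (fresh weights from ``rng``)."""
    if spec.has_bias or not spec.has_bn or spec.activation != "silu":
        raise ConfigError("CBS requires bias-free conv + BN + SiLU")
    return Conv(spec, rng if rng is not None else np.random.default_rng(0)).forward(x)


class SPPF:
    """Fast spatial pyramid pooling: 1x1 CBS to C/2, three chained 5x5
    stride-1 max-pools, concat of the four stages, 1x1 CBS back to C."""

    def __init__(self, channels: int, rng: np.random.Generator, pool_kernel: int = 5):
        if channels % 2 != 0:
            raise ConfigError("SPPF channel count must be even")
        self.channels = channels
        self.hidden = channels // 2
        self.pool_kernel = pool_kernel
        self.cv1 = CBS(channels, self.hidden, kernel=1, rng=rng)
        self.cv2 = CBS(self.hidden * 4, channels, kernel=1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y0 = self.cv1(x)
        p = (self.pool_kernel - 1) // 2
        y1 = max_pool(y0, self.pool_kernel, 1, p)
        y2 = max_pool(y1, self.pool_kernel, 1, p)
        y3 = max_pool(y2, self.pool_kernel, 1, p)
        return self.cv2(np.concatenate([y0, y1, y2, y3], axis=2))

    __call__ = forward

    def param_count(self) -> int:
        return self.cv1.param_count() + self.cv2.param_count()

    def macs(self, out_h: int, out_w: int) -> int:
        return self.cv1.macs(out_h, out_w) + self.cv2.macs(out_h, out_w)


class ALSS:
    """Adaptive lightweight split-and-shuffle block.

    Channel split into shortcut and main paths; the main path runs a
    1x1-reduce, 3x3 (strided), 1x1-expand CBS bottleneck; at stride 2 the
    shortcut is downsampled by a depthwise 3x3 CBS.  Paths are concatenated
    and channel-shuffled (2 groups when the output width is even).
    """

    def __init__(self, cfg: ALSSConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg
        self.reduce = CBS(c.main_in_channels, c.bottleneck_channels, kernel=1, rng=rng)
        self.mix = CBS(c.bottleneck_channels, c.bottleneck_channels, kernel=3, stride=c.stride, rng=rng)
        self.expand = CBS(c.bottleneck_channels, c.main_out_channels, kernel=1, rng=rng)
        self.shortcut_down = None
        if c.stride == 2:
            self.shortcut_down = CBS(
                c.shortcut_channels, c.shortcut_channels, kernel=3, stride=2, depthwise=True, rng=rng
            )
        self.shuffle_groups = 2 if c.out_channels % 2 == 0 else 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = self.cfg
        if x.shape[2] != c.in_channels:
            raise ShapeError(f"expected {c.in_channels} channels, got {x.shape[2]}")
        shortcut = x[:, :, : c.shortcut_channels]
        main = x[:, :, c.shortcut_channels :]
        if self.shortcut_down is not None:
            shortcut = self.shortcut_down(shortcut)
        main = self.expand(self.mix(self.reduce(main)))
        return channel_shuffle(np.concatenate([shortcut, main], axis=2), self.shuffle_groups)

    __call__ = forward

    def param_count(self) -> int:
        total = self.reduce.param_count() + self.mix.param_count() + self.expand.param_count()
        if self.shortcut_down is not None:
            total += self.shortcut_down.param_count()
        return total

    def macs(self, out_h: int, out_w: int) -> int:
        in_h, in_w = out_h * self.cfg.stride, out_w * self.cfg.stride
        total = self.reduce.macs(in_h, in_w) + self.mix.macs(out_h, out_w) + self.expand.macs(out_h, out_w)
        if self.shortcut_down is not None:
            total += self.shortcut_down.macs(out_h, out_w)
        return total


class MSCA:
    """Multi-scale channel attention.

    A 3x3 bias-free convolution compresses C channels to r = max(1,
    floor(alpha*C)).  Four branches adaptively average-pool the compressed map
    to s in (1, 3, 3, 5) and apply a bias-free depthwise s x s convolution
    with no padding, each collapsing to a 1x1xr descriptor.  The concatenated
    4r-vector is expanded back to C by a bias-free 1x1 convolution and squashed
    by the logistic function into per-channel weights in (0, 1) that rescale
    the input.  No batch norm and no activations inside the block.
    """

    def __init__(self, cfg: MSCAConfig, rng: np.random.Generator):
        self.cfg = cfg
        r = cfg.reduced
        self.reduce = Conv(
            ConvSpec(cfg.channels, r, kernel=3, has_bias=False, has_bn=False, activation="none"),
            rng,
        )
        self.branches = []
        for k in cfg.dw_kernels:
            self.branches.append(
                Conv(
                    ConvSpec(r, r, kernel=k, padding=0, depthwise=True,
                             has_bias=False, has_bn=False, activation="none"),
                    rng,
                )
            )
        self.expand = Conv(
            ConvSpec(len(cfg.pool_sizes) * r, cfg.channels, kernel=1,
                     has_bias=False, has_bn=False, activation="none"),
            rng,
        )

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention weights in (0, 1) for a (H, W, C) input."""
        z = self.reduce(x)
        feats = []
        for size, conv in zip(self.cfg.pool_sizes, self.branches):
            pooled = adaptive_avg_pool(z, size)
            feats.append(conv(pooled))  # (1, 1, r)
        gcat = np.concatenate(feats, axis=2)
        logits = self.expand(gcat)[0, 0]
        return sigmoid(logits)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.cfg.channels:
            raise ShapeError(
                f"expected {self.cfg.channels} channels, got {x.shape[2]}"
            )
        return x * self.attention(x)

    __call__ = forward

    def param_count(self) -> int:
        return msca_param_count(self.cfg)

    def macs(self, out_h: int, out_w: int) -> int:
        total = self.reduce.macs(out_h, out_w)
        for size, conv in zip(self.cfg.pool_sizes, self.branches):
            total += conv.macs(1, 1)
        total += self.expand.macs(1, 1)
        return total
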