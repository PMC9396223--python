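"""Detector architecture family: YOLOv5s-6.0 baseline and its lightweight rungs.

The family covers the ablation ladder of the litchi detector:

* ``csp_darknet53`` backbone — the stock YOLOv5s version-6.0 layout
  (CBS/C3/SPPF at width multiple 0.5, depth multiple 0.33);
* ``shufflenet_v2`` backbone — ShuffleNet v2 1.0x stages (channels
  116/232/464, repeats 4/8/4) behind a 6x6 stride-2 stem and a 3x3
  stride-2 max-pool, with SPPF on the last stage;
* optional CBAM attention on each backbone tap feeding the neck;
* optional "head cut": the stride-32 detection head and its bottom-up
  neck limb are removed, leaving heads at strides 8 and 16 for
  small-object-only scenes.

Parameter counts are reported in two conventions.  ``deployed`` folds
each convolution with its batch norm (weight plus one bias per output
channel) — the convention under which the published counts of this
model family are quoted; ``training`` counts the unfolded layers
(conv weights plus two affine parameters per BN channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "VariantSpec", "ParamReport", "CBAM_LADDER_CONVENTION",
    "channel_shuffle", "ConvBN", "C3", "SPPF", "ShuffleV2Block", "CBAM",
    "DetectionModel", "build_variant", "count_parameters", "VARIANTS",
]

# Default prior boxes (w, h at 640-px scale), three per detection scale,
# ascending by area; re-estimated from data with kmeans_anchors in practice.
DEFAULT_ANCHORS_3 = (
    ((10, 13), (16, 30), (33, 23)),      # stride 8
    ((30, 61), (62, 45), (59, 119)),     # stride 16
    ((116, 90), (156, 198), (373, 326)),  # stride 32
)

# CBAM construction convention that reproduces the published ablation
# ladder of the ShuffleNet rows (channel-MLP hidden bias on, spatial
# conv followed by an unfused BN).  The default convention (both off)
# reproduces the published CBAM delta on the 128/256/512 baseline taps.
CBAM_LADDER_CONVENTION = {"cam_hidden_bias": True, "sam_batchnorm": True}


@dataclass
class VariantSpec:
    """Which rung of the ablation ladder to build."""

    backbone: str = "csp_darknet53"           # or "shufflenet_v2"
    use_cbam: bool = False
    input_size: int = 640                     # 640 or 1280; any multiple of 32 runs
    head_cut: bool = False
    nc: int = 2
    stem_channels: int = 24                   # shufflenet stem width
    cbam_reduction: int = 16
    cbam_hidden_round: str = "floor"          # floor | ceil | round
    cam_hidden_bias: bool = False
    sam_batchnorm: bool = False
    anchors: Optional[tuple] = None           # ((w,h)*3,) per scale, input-px units

    def __post_init__(self):
        if self.backbone not in ("csp_darknet53", "shufflenet_v2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")
        if self.nc < 1:
            raise ValueError("nc must be >= 1")

    @property
    def n_heads(self):
        return 2 if self.head_cut else 3

    @property
    def strides(self):
        return (8, 16) if self.head_cut else (8, 16, 32)

    def resolved_anchors(self):
        if self.anchors is not None:
            anchors = self.anchors
        else:
            scale = self.input_size / 640.0
            anchors = tuple(tuple((w * scale, h * scale) for w, h in level)
                            for level in DEFAULT_ANCHORS_3)
        return anchors[: self.n_heads]


@dataclass
class ParamReport:
    total: int
    breakdown: list = field(default_factory=list)  # (name, count)
    convention: str = "deployed"

    def __str__(self):
        lines = [f"{'module':<28}{'params':>12}"]
        for name, count in self.breakdown:
            lines.append(f"{name:<28}{count:>12,}")
        lines.append(f"{'total (' + self.convention + ')':<28}{self.total:>12,}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups: reshape (g, C/g) -> transpose -> flatten.

    For C channels and g groups, channel i maps to position
    ``(i % (C/g)) * g + i // (C/g)``; spatial content is untouched.
    """
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


def autopad(k):
    return k // 2


class ConvBN(nn.Module):
    """Conv2d + BatchNorm2d + activation (the CBS block)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="silu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, autopad(k) if p is None else p,
                              groups=g, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c2)
        self.act = {"silu": nn.SiLU(), "relu": nn.ReLU(), None: nn.Identity(),
                    "none": nn.Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBN(c1, c2, 1, rng=rng)
        self.cv2 = ConvBN(c2, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """CSP residual block: two 1x1 branches, bottleneck stack, 1x1 merge."""

    def __init__(self, c1, c2, n=1, shortcut=True, rng=None):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = ConvBN(c1, c_, 1, rng=rng)
        self.cv2 = ConvBN(c1, c_, 1, rng=rng)
        self.cv3 = ConvBN(2 * c_, c2, 1, rng=rng)
        self.m = [Bottleneck(c_, c_, shortcut, rng=rng) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(Tensor.concat([y, self.cv2(x)], axis=1))


class SPPF(nn.Module):
    """Fast spatial pyramid pooling: three serial 5x5 max-pools, concat."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBN(c1, c_, 1, rng=rng)
        self.cv2 = ConvBN(4 * c_, c2, 1, rng=rng)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(Tensor.concat([y, p1, p2, p3], axis=1))


class ShuffleV2Block(nn.Module):
    """ShuffleNet v2 unit (ShuBlock).

    stride 1: channel split into halves; the right branch is
    1x1 -> 3x3 depthwise -> 1x1; concat and channel shuffle.
    stride 2: both branches downsample (left 3x3 dw s2 + 1x1; right
    1x1 + 3x3 dw s2 + 1x1); concat doubles the channel count.
    """

    def __init__(self, c1, c2, stride, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if stride == 1 and c1 != c2:
            raise ValueError("stride-1 ShuBlock requires in == out channels")
        if stride == 1 and c1 % 2:
            raise ValueError("stride-1 ShuBlock requires even channels")
        self.stride = stride
        bf = c2 // 2
        if stride == 2:
            self.left = nn.Sequential(
                ConvBN(c1, c1, 3, 2, g=c1, act=None, rng=rng),
                ConvBN(c1, bf, 1, act="relu", rng=rng))
            right_in = c1
        else:
            self.left = None
            right_in = c1 // 2
        self.right = nn.Sequential(
            ConvBN(right_in, bf, 1, act="relu", rng=rng),
            ConvBN(bf, bf, 3, stride, g=bf, act=None, rng=rng),
            ConvBN(bf, bf, 1, act="relu", rng=rng))

    def forward(self, x):
        if self.stride == 1:
            c = x.shape[1] // 2
            xl, xr = x[:, :c], x[:, c:]
            out = Tensor.concat([xl, self.right(xr)], axis=1)
        else:
            out = Tensor.concat([self.left(x), self.right(x)], axis=1)
        return channel_shuffle(out, 2)


class ChannelAttention(nn.Module):
    """CAM: global max & avg pooled descriptors through a shared MLP."""

    def __init__(self, channels, reduction=16, hidden_round="floor",
                 hidden_bias=False, rng=None):
        super().__init__()
        ratio = channels / reduction
        hidden = {"floor": int(np.floor(ratio)), "ceil": int(np.ceil(ratio)),
                  "round": int(round(ratio))}[hidden_round]
        hidden = max(hidden, 1)
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=hidden_bias, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=False, rng=rng)

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        mx = x.max_spatial().reshape(n, c, 1, 1)
        av = x.mean(axis=(2, 3), keepdims=True)
        attn = (self.fc2(self.fc1(mx).relu()) + self.fc2(self.fc1(av).relu())).sigmoid()
        return x * attn


class SpatialAttention(nn.Module):
    """SAM: channel-wise max & mean maps, 7x7 conv, sigmoid gate."""

    def __init__(self, kernel=7, batchnorm=False, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(1) if batchnorm else None

    def forward(self, x):
        mx = x.max_channel(keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        y = self.conv(Tensor.concat([mx, av], axis=1))
        if self.bn is not None:
            y = self.bn(y)
        return x * y.sigmoid()


class CBAM(nn.Module):
    """Serial channel-then-spatial attention; output shape = input shape."""

    def __init__(self, channels, reduction=16, hidden_round="floor",
                 cam_hidden_bias=False, sam_batchnorm=False, rng=None):
        super().__init__()
        self.cam = ChannelAttention(channels, reduction, hidden_round,
                                    cam_hidden_bias, rng=rng)
        self.sam = SpatialAttention(7, sam_batchnorm, rng=rng)

    def forward(self, x):
        return self.sam(self.cam(x))


class Detect(nn.Module):
    """Per-scale 1x1 prediction convolutions, 3 anchors x (5 + nc) outputs."""

    def __init__(self, channels, nc, strides, input_size, rng=None):
        super().__init__()
        self.nc = nc
        self.na = 3
        self.strides = tuple(strides)
        out = self.na * (5 + nc)
        self.convs = [nn.Conv2d(c, out, 1, bias=True, rng=rng) for c in channels]
        # bias the objectness outputs low so the net starts sparse
        for conv, s in zip(self.convs, self.strides):
            b = conv.bias.data.reshape(self.na, 5 + nc)
            b[:, 4] += np.log(8 / (input_size / s) ** 2)
            b[:, 5:] += np.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0

    def forward(self, feats):
        return [conv(f) for conv, f in zip(self.convs, feats)]


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

class _CSPBackbone(nn.Module):
    def __init__(self, rng):
        super().__init__()
        self.layers = [
            ConvBN(3, 32, 6, 2, 2, rng=rng),        # P1/2
            ConvBN(32, 64, 3, 2, rng=rng),          # P2/4
            C3(64, 64, 1, rng=rng),
            ConvBN(64, 128, 3, 2, rng=rng),         # P3/8
            C3(128, 128, 2, rng=rng),
            ConvBN(128, 256, 3, 2, rng=rng),        # P4/16
            C3(256, 256, 3, rng=rng),
            ConvBN(256, 512, 3, 2, rng=rng),        # P5/32
            C3(512, 512, 1, rng=rng),
            SPPF(512, 512, rng=rng),
        ]
        self.tap_channels = (128, 256, 512)
        self.tap_indices = (4, 6, 9)

    def forward(self, x):
        taps = []
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i in self.tap_indices:
                taps.append(x)
        return taps


class _ShuffleBackbone(nn.Module):
    def __init__(self, stem_channels, rng):
        super().__init__()
        self.stem = ConvBN(3, stem_channels, 6, 2, 2, rng=rng)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        c = stem_channels
        for out, reps in ((116, 4), (232, 8), (464, 4)):
            blocks = [ShuffleV2Block(c, out, 2, rng=rng)]
            blocks += [ShuffleV2Block(out, out, 1, rng=rng) for _ in range(reps - 1)]
            self.stages.append(blocks)
            c = out
        self.sppf = SPPF(464, 464, rng=rng)
        self.tap_channels = (116, 232, 464)

    def forward(self, x):
        x = self.pool(self.stem(x))
        taps = []
        for i, stage in enumerate(self.stages):
            for block in stage:
                x = block(x)
            taps.append(x)
        taps[-1] = self.sppf(taps[-1])
        return taps


class _PANetNeck(nn.Module):
    """Top-down + bottom-up feature fusion; ``cut`` drops the P5 limb."""

    def __init__(self, ch, cut, rng):
        super().__init__()
        c3_, c4_, c5_ = ch
        self.cut = cut
        self.reduce5 = ConvBN(c5_, c4_, 1, rng=rng)
        self.up = nn.UpsampleNearest2x()
        self.td4 = C3(2 * c4_, c4_, 1, shortcut=False, rng=rng)
        self.reduce4 = ConvBN(c4_, c3_, 1, rng=rng)
        self.td3 = C3(2 * c3_, c3_, 1, shortcut=False, rng=rng)
        self.down3 = ConvBN(c3_, c3_, 3, 2, rng=rng)
        self.bu4 = C3(2 * c3_, c4_, 1, shortcut=False, rng=rng)
        if not cut:
            self.down4 = ConvBN(c4_, c4_, 3, 2, rng=rng)
            self.bu5 = C3(2 * c4_, c5_, 1, shortcut=False, rng=rng)
        self.out_channels = (c3_, c4_) if cut else (c3_, c4_, c5_)

    def forward(self, taps):
        p3, p4, p5 = taps
        r5 = self.reduce5(p5)
        t4 = self.td4(Tensor.concat([self.up(r5), p4], axis=1))
        r4 = self.reduce4(t4)
        t3 = self.td3(Tensor.concat([self.up(r4), p3], axis=1))
        b4 = self.bu4(Tensor.concat([self.down3(t3), r4], axis=1))
        if self.cut:
            return [t3, b4]
        b5 = self.bu5(Tensor.concat([self.down4(b4), r5], axis=1))
        return [t3, b4, b5]


class DetectionModel(nn.Module):
    """A buildable rung of the detector ablation ladder."""

    def __init__(self, spec: VariantSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        if spec.backbone == "csp_darknet53":
            self.backbone = _CSPBackbone(rng)
        else:
            self.backbone = _ShuffleBackbone(spec.stem_channels, rng)
        ch = self.backbone.tap_channels
        if spec.use_cbam:
            self.cbam = [CBAM(c, spec.cbam_reduction, spec.cbam_hidden_round,
                              spec.cam_hidden_bias, spec.sam_batchnorm, rng=rng)
                         for c in ch]
        else:
            self.cbam = None
        self.neck = _PANetNeck(ch, spec.head_cut, rng)
        self.detect = Detect(self.neck.out_channels, spec.nc, spec.strides,
                             spec.input_size, rng=rng)

    def forward_features(self, x):
        taps = self.backbone(x)
        if self.cbam is not None:
            taps = [m(t) for m, t in zip(self.cbam, taps)]
        return self.neck(taps)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return self.detect(self.forward_features(x))


# ---------------------------------------------------------------------------
# parameter audit
# ---------------------------------------------------------------------------

def _count(module, deployed):
    if isinstance(module, ConvBN):
        w = module.conv.weight.size
        return w + (module.bn.ch if deployed else 2 * module.bn.ch)
    if isinstance(module, nn.Conv2d):
        return module.weight.size + (module.bias.size if module.bias is not None else 0)
    if isinstance(module, nn.BatchNorm2d):
        return module.weight.size + module.bias.size
    total = 0
    for value in vars(module).values():
        if isinstance(value, nn.Module):
            total += _count(value, deployed)
        elif isinstance(value, (list, tuple)):
            total += sum(_count(v, deployed) for v in _flatten_modules(value))
    return total


def _flatten_modules(seq):
    for item in seq:
        if isinstance(item, (list, tuple)):
            yield from _flatten_modules(item)
        elif isinstance(item, nn.Module):
            yield item


def count_parameters(model: DetectionModel, convention: str = "deployed") -> ParamReport:
    """Audit trainable parameters.

    ``deployed``: each conv+BN pair folded to conv weight + per-channel
    bias (the convention the published counts use); standalone BNs keep
    their two affine terms.  ``training``: BN affine counted as two
    parameters per channel everywhere.
    """
    if convention not in ("deployed", "training"):
        raise ValueError("convention must be 'deployed' or 'training'")
    deployed = convention == "deployed"
    breakdown = [("backbone", _count(model.backbone, deployed))]
    if model.cbam is not None:
        for i, m in enumerate(model.cbam):
            breakdown.append((f"cbam.p{i + 3}", _count(m, deployed)))
    breakdown.append(("neck", _count(model.neck, deployed)))
    breakdown.append(("detect", _count(model.detect, deployed)))
    return ParamReport(sum(c for _, c in breakdown), breakdown, convention)


# ---------------------------------------------------------------------------
# named variants (the ablation ladder)
# ---------------------------------------------------------------------------

VARIANTS = {
    "yolov5s": VariantSpec(),
    "yolov5s_cbam": VariantSpec(use_cbam=True),
    "yolov5s_1280": VariantSpec(input_size=1280),
    "shufflenet": VariantSpec(backbone="shufflenet_v2"),
    "shufflenet_cbam": VariantSpec(backbone="shufflenet_v2", use_cbam=True,
                                   **CBAM_LADDER_CONVENTION),
    "shufflenet_cbam_1280": VariantSpec(backbone="shufflenet_v2", use_cbam=True,
                                        input_size=1280, **CBAM_LADDER_CONVENTION),
    "full_cut": VariantSpec(backbone="shufflenet_v2", use_cbam=True,
                            input_size=1280, head_cut=True,
                            **CBAM_LADDER_CONVENTION),
}


def build_variant(spec, seed: int = 0, **overrides) -> DetectionModel:
    """Build a model from a VariantSpec or a registered variant name."""
    if isinstance(spec, str):
        try:
            spec = VARIANTS[spec]
        except KeyError:
            raise KeyError(f"unknown variant {spec!r}; known: {sorted(VARIANTS)}") from None
    if overrides:
        spec = replace(spec, **overrides)
    return DetectionModel(spec, seed=seed)
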