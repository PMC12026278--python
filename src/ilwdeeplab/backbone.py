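"""EfficientNet-B1 feature extractor with two taps (stride 4 and stride 16).

The network follows the compound-scaled B1 layout: the B0 stage table with
depth multiplier 1.1 (repeats [2,3,3,4,4,5,2]) and unit width multiplier.
Every block is a mobile inverted bottleneck (MBConv): pointwise expansion,
depthwise convolution, squeeze-and-excitation gate on the expanded channels
(squeeze width = block input channels / 4), pointwise projection, with a
residual connection when shapes allow. The stage that would reach stride 32
runs with unit stride and dilation 2 instead, so the high-level tap stays at
1/16 resolution — the standard DeepLabv3+ adaptation.

The canonical classification variant ends with a 1280-channel pointwise
projection. The segmentation graph never executes it, but the published
complexity figures this package reproduces count a model object that still
holds those weights, so the extractor retains them as a vestigial head
(``include_vestigial_head``); see docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Module, Sequential,
                 Sigmoid, SiLU)

# B0 stage table: (repeats, kernel, stride, expansion, out_channels)
_B0_STAGES = [(1, 3, 1, 1, 16), (2, 3, 2, 6, 24), (2, 5, 2, 6, 40),
              (3, 3, 2, 6, 80), (3, 5, 1, 6, 112), (4, 5, 2, 6, 192),
              (1, 3, 1, 6, 320)]
_B1_DEPTH = 1.1
STEM_CHANNELS = 32
LOW_LEVEL_CHANNELS = 24
HIGH_LEVEL_CHANNELS = 320
VESTIGIAL_HEAD_CHANNELS = 1280
# Batch-norm settings: EfficientNet's epsilon, but a faster running-stat
# momentum (0.1) than the reference 0.01 — the published complexity figures
# are unaffected, and short training runs need inference statistics that
# actually track the batch statistics (see docs/methods.md).
BN_EPS = 1e-3
BN_MOMENTUM = 0.1


def b1_stage_table() -> list[tuple[int, int, int, int, int]]:
    """(repeats, kernel, stride, expansion, out_channels) after depth scaling."""
    return [(int(np.ceil(_B1_DEPTH * r)), k, s, e, c)
            for (r, k, s, e, c) in _B0_STAGES]


@dataclass
class BackboneSpec:
    """Configuration of the hierarchical extractor."""
    name: str = "efficientnet-b1"
    stages: list[tuple[int, int, int, int, int]] = field(default_factory=b1_stage_table)
    stem_channels: int = STEM_CHANNELS
    se_reduction: int = 4            # squeeze width = block input channels / 4
    output_stride: int = 16
    include_vestigial_head: bool = True
    bn_eps: float = BN_EPS
    bn_momentum: float = BN_MOMENTUM

    def __post_init__(self):
        if self.output_stride != 16:
            raise ValueError("only output stride 16 is supported")
        if any(c <= 0 for (_, _, _, _, c) in self.stages):
            raise ValueError("stage widths must be positive")


@dataclass
class FeaturePair:
    """Backbone outputs: 1/4-resolution and 1/16-resolution feature maps."""
    low: np.ndarray
    high: np.ndarray


class SqueezeExciteGate(Module):
    """MBConv-internal SE: pool -> 1x1 (bias) -> SiLU -> 1x1 (bias) -> sigmoid -> scale."""

    def __init__(self, channels: int, squeezed: int, rng):
        super().__init__()
        self.pool = GlobalAvgPool()
        self.fc1 = Conv2d(channels, squeezed, 1, bias=True, rng=rng)
        self.act = SiLU()
        self.fc2 = Conv2d(squeezed, channels, 1, bias=True, rng=rng)
        self.gate = Sigmoid()
        self._cache = None

    def forward(self, x, training: bool = False):
        s = self.pool.forward(x, training)
        s = self.fc1.forward(s, training)
        s = self.act.forward(s, training)
        s = self.fc2.forward(s, training)
        g = self.gate.forward(s, training)
        if training:
            self._cache = (x, g)
        return x * g

    def backward(self, grad):
        x, g = self._cache
        gg = (grad * x).sum(axis=(2, 3), keepdims=True)
        gx = grad * g
        gs = self.gate.backward(gg)
        gs = self.fc2.backward(gs)
        gs = self.act.backward(gs)
        gs = self.fc1.backward(gs)
        gx += self.pool.backward(gs)
        return gx


class MBConv(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, expansion: int,
                 dilation: int, se_reduction: int, bn_eps: float,
                 bn_momentum: float, rng):
        super().__init__()
        ce = cin * expansion
        self.use_residual = stride == 1 and cin == cout
        if expansion != 1:
            self.expand = Sequential(
                Conv2d(cin, ce, 1, bias=False, rng=rng),
                BatchNorm2d(ce, bn_eps, bn_momentum), SiLU())
        else:
            self.expand = None
        self.dw = Sequential(
            Conv2d(ce, ce, k, stride=stride, dilation=dilation, groups=ce,
                   bias=False, rng=rng),
            BatchNorm2d(ce, bn_eps, bn_momentum), SiLU())
        squeezed = max(1, cin // se_reduction)
        self.se = SqueezeExciteGate(ce, squeezed, rng)
        self.project = Sequential(
            Conv2d(ce, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout, bn_eps, bn_momentum))

    def forward(self, x, training: bool = False):
        h = x
        if self.expand is not None:
            h = self.expand.forward(h, training)
        h = self.dw.forward(h, training)
        h = self.se.forward(h, training)
        h = self.project.forward(h, training)
        if self.use_residual:
            h = h + x
        return h

    def backward(self, grad):
        g = self.project.backward(grad)
        g = self.se.backward(g)
        g = self.dw.backward(g)
        if self.expand is not None:
            g = self.expand.backward(g)
        if self.use_residual:
            g = g + grad
        return g


class EfficientNetB1(Module):
    """Feature extractor; ``forward`` returns a :class:`FeaturePair`."""

    def __init__(self, spec: BackboneSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec or BackboneSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.stem = Sequential(
            Conv2d(3, s.stem_channels, 3, stride=2, bias=False, rng=rng),
            BatchNorm2d(s.stem_channels, s.bn_eps, s.bn_momentum), SiLU())
        blocks: list[MBConv] = []
        cin = s.stem_channels
        cum_stride, dilation = 2, 1
        self.low_tap_index = -1
        for si, (reps, k, stride, e, cout) in enumerate(s.stages):
            for b in range(reps):
                blk_stride = stride if b == 0 else 1
                if blk_stride > 1 and cum_stride * blk_stride > s.output_stride:
                    dilation *= blk_stride
                    blk_stride = 1
                elif blk_stride > 1:
                    cum_stride *= blk_stride
                blocks.append(MBConv(cin, cout, k, blk_stride, e, dilation,
                                     s.se_reduction, s.bn_eps, s.bn_momentum,
                                     rng))
                cin = cout
            if cum_stride == 4 and self.low_tap_index < 0 and cout == LOW_LEVEL_CHANNELS:
                self.low_tap_index = len(blocks) - 1
        if self.low_tap_index < 0:
            raise RuntimeError("no stride-4 tap found in stage table")
        self.blocks = blocks
        self.out_channels = cin
        if s.include_vestigial_head:
            # parameters retained for complexity parity; never executed
            self.vestigial_head = Sequential(
                Conv2d(cin, VESTIGIAL_HEAD_CHANNELS, 1, bias=False, rng=rng),
                BatchNorm2d(VESTIGIAL_HEAD_CHANNELS, s.bn_eps, s.bn_momentum))
        else:
            self.vestigial_head = None

    def forward(self, x, training: bool = False) -> FeaturePair:
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"input side must be divisible by 16, got {h}x{w}")
        h_ = self.stem.forward(x, training)
        low = None
        for i, blk in enumerate(self.blocks):
            h_ = blk.forward(h_, training)
            if i == self.low_tap_index:
                low = h_
        return FeaturePair(low=low, high=h_)

    def backward(self, grad_low, grad_high):
        g = grad_high
        for i in range(len(self.blocks) - 1, -1, -1):
            g = self.blocks[i].backward(g)
            if i == self.low_tap_index:
                g = g + grad_low
        return self.stem.backward(g)

    def load_weights(self, archive: dict[str, np.ndarray]) -> None:
        """Hook for externally supplied pretrained weights (flat name->array)."""
        self.load_state_dict(archive)


def build_efficientnet_b1(spec: BackboneSpec | None = None,
                          seed: int = 0) -> EfficientNetB1:
    return EfficientNetB1(spec, seed=seed)


def extract(extractor: EfficientNetB1, batch: np.ndarray) -> FeaturePair:
    """Evaluation-mode feature extraction (deterministic)."""
    return extractor.forward(batch.astype(np.float32), training=False)
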