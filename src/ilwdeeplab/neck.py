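"""Multi-scale context modules: ASPP and its cascaded-waterfall variant.

ASPP runs parallel atrous branches at large rates plus image pooling. The
waterfall variant (CWASPP) first reduces the 320-channel encoder output with
a 1x1 convolution, then chains separable 3x3 atrous convolutions with small
progressive rates — each stage consumes its predecessor's output — avoiding
the gridding artifacts of large dilations while cutting parameters. Stage
outputs, the reduced input and an image-pooling branch are concatenated and
fused to 256 channels.

Channel widths follow the calibration in docs/methods.md: they are fixed so
that the assembled lightweight model reproduces the published parameter
totals exactly. The image-pool width (52) in particular is a calibration
artifact, not a claim about elegance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Module, ReLU, Sequential)

NECK_OUT_CHANNELS = 256  # pinned by the attention parameter contracts


@dataclass
class NeckConfig:
    mode: str = "cwaspp"                       # "aspp" | "cwaspp"
    rates: tuple[int, ...] = (2, 4, 6)
    in_channels: int = 320
    reduced_channels: int = 48                 # cwaspp input 1x1 width
    branch_channels: int = 48                  # cascade stage width
    pool_channels: int = 52                    # image-pool branch width (calibrated)
    out_channels: int = NECK_OUT_CHANNELS
    include_image_pooling: bool = True

    def __post_init__(self):
        if self.mode not in ("aspp", "cwaspp"):
            raise ValueError(f"unknown neck mode {self.mode!r}")
        if any(r <= 0 for r in self.rates):
            raise ValueError("dilation rates must be strictly positive")
        if self.mode == "cwaspp" and list(self.rates) != sorted(set(self.rates)):
            raise ValueError("waterfall rates must be strictly increasing")
        if self.out_channels != NECK_OUT_CHANNELS:
            raise ValueError("out_channels is pinned to 256")


def aspp_default_config() -> NeckConfig:
    return NeckConfig(mode="aspp", rates=(12, 24, 36))


class SeparableConv(Module):
    """Depthwise k x k followed by pointwise 1x1 (both bias-free)."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng=None):
        super().__init__()
        self.depthwise = Conv2d(cin, cin, k, dilation=dilation, groups=cin,
                                bias=False, rng=rng)
        self.pointwise = Conv2d(cin, cout, 1, bias=False, rng=rng)

    @property
    def dilation(self) -> int:
        return self.depthwise.dilation

    def forward(self, x, training: bool = False):
        return self.pointwise.forward(self.depthwise.forward(x, training),
                                      training)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))


class _ImagePool(Module):
    """Global pool -> 1x1 conv -> ReLU, broadcast back to the input grid."""

    def __init__(self, cin: int, cout: int, rng, with_bn: bool = False,
                 bias: bool = False):
        super().__init__()
        self.pool = GlobalAvgPool()
        self.conv = Conv2d(cin, cout, 1, bias=bias, rng=rng)
        self.bn = BatchNorm2d(cout) if with_bn else None
        self.act = ReLU()
        self._hw = None

    def forward(self, x, training: bool = False):
        self._hw = x.shape[2:]
        s = self.pool.forward(x, training)
        s = self.conv.forward(s, training)
        if self.bn is not None:
            s = self.bn.forward(s, training)
        s = self.act.forward(s, training)
        h, w = self._hw
        return np.broadcast_to(s, s.shape[:2] + (h, w)).copy()

    def backward(self, grad):
        g = grad.sum(axis=(2, 3), keepdims=True)
        g = self.act.backward(g)
        if self.bn is not None:
            g = self.bn.backward(g)
        g = self.conv.backward(g)
        return self.pool.backward(g)


class CWASPP(Module):
    """Cascaded waterfall atrous pooling (see module docstring)."""

    def __init__(self, cfg: NeckConfig, rng=None):
        super().__init__()
        if cfg.mode != "cwaspp":
            raise ValueError("config mode must be 'cwaspp'")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        R, W = cfg.reduced_channels, cfg.branch_channels
        self.reduce = Conv2d(cfg.in_channels, R, 1, bias=False, rng=rng)
        self.reduce_act = ReLU()
        stages, acts, cin = [], [], R
        for rate in cfg.rates:
            stages.append(SeparableConv(cin, W, 3, dilation=rate, rng=rng))
            acts.append(ReLU())
            cin = W
        self.stages = stages
        self.stage_acts = acts
        if cfg.include_image_pooling:
            self.image_pool = _ImagePool(cfg.in_channels, cfg.pool_channels, rng)
        else:
            self.image_pool = None
        concat = R + W * len(cfg.rates) + (cfg.pool_channels if self.image_pool else 0)
        self.concat_channels = concat
        self.project = Conv2d(concat, cfg.out_channels, 1, bias=True, rng=rng)
        self.project_bn = BatchNorm2d(cfg.out_channels)
        self.project_act = ReLU()
        self._split = None

    def forward(self, x, training: bool = False):
        r = self.reduce_act.forward(self.reduce.forward(x, training), training)
        outs = [r]
        h = r
        for stage, act in zip(self.stages, self.stage_acts):
            h = act.forward(stage.forward(h, training), training)
            outs.append(h)
        if self.image_pool is not None:
            outs.append(self.image_pool.forward(x, training))
        cat = np.concatenate(outs, axis=1)
        if training:
            self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        out = self.project.forward(cat, training)
        out = self.project_bn.forward(out, training)
        return self.project_act.forward(out, training)

    def backward(self, grad):
        g = self.project_act.backward(grad)
        g = self.project_bn.backward(g)
        g = self.project.backward(g)
        parts = np.split(g, self._split, axis=1)
        gx = 0.0
        if self.image_pool is not None:
            gx = gx + self.image_pool.backward(parts.pop())
        gcarry = None
        for stage, act, gpart in zip(reversed(self.stages),
                                     reversed(self.stage_acts),
                                     reversed(parts[1:])):
            gtot = gpart if gcarry is None else gpart + gcarry
            gcarry = stage.backward(act.backward(gtot))
        gr = parts[0] if gcarry is None else parts[0] + gcarry
        gr = self.reduce_act.backward(gr)
        return gx + self.reduce.backward(gr)


class ASPP(Module):
    """Parallel atrous pooling with separable branches (decoder dialect)."""

    def __init__(self, cfg: NeckConfig, rng=None):
        super().__init__()
        if cfg.mode != "aspp":
            raise ValueError("config mode must be 'aspp'")
        if len(cfg.rates) != 3:
            raise ValueError("aspp uses exactly three atrous rates")
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        cin, cout = cfg.in_channels, cfg.out_channels
        self.branch0 = Sequential(Conv2d(cin, cout, 1, bias=False, rng=rng),
                                  BatchNorm2d(cout), ReLU())
        self.branches = [
            Sequential(SeparableConv(cin, cout, 3, dilation=r, rng=rng),
                       BatchNorm2d(cout), ReLU())
            for r in cfg.rates
        ]
        self.image_pool = _ImagePool(cin, cout, rng, with_bn=True)
        n_branch = 4 + (1 if cfg.include_image_pooling else 0)
        self.project = Conv2d(n_branch * cout, cout, 1, bias=False, rng=rng)
        self.project_bn = BatchNorm2d(cout)
        self.project_act = ReLU()
        self._split = None

    def forward(self, x, training: bool = False):
        outs = [self.branch0.forward(x, training)]
        outs += [b.forward(x, training) for b in self.branches]
        if self.cfg.include_image_pooling:
            outs.append(self.image_pool.forward(x, training))
        cat = np.concatenate(outs, axis=1)
        if training:
            self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        out = self.project.forward(cat, training)
        out = self.project_bn.forward(out, training)
        return self.project_act.forward(out, training)

    def backward(self, grad):
        g = self.project_act.backward(grad)
        g = self.project_bn.backward(g)
        g = self.project.backward(g)
        parts = np.split(g, self._split, axis=1)
        gx = self.branch0.backward(parts[0])
        for b, gp in zip(self.branches, parts[1:4]):
            gx = gx + b.backward(gp)
        if self.cfg.include_image_pooling:
            gx = gx + self.image_pool.backward(parts[4])
        return gx


def build_aspp(cfg: NeckConfig | None = None, rng=None) -> ASPP:
    return ASPP(cfg or aspp_default_config(), rng=rng)


def build_cwaspp(cfg: NeckConfig | None = None, rng=None) -> CWASPP:
    return CWASPP(cfg or NeckConfig(), rng=rng)
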