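"""Trainable-parameter and multiply–accumulate (MAC) profiling.

Two frozen counting conventions are provided (see docs/methods.md for the
calibration):

``published``
    Reproduces the complexity figures reported for this architecture family.
    Rules: convolution = out_elements x (cin/groups) x k^2; batch norm =
    4 x elements (normalise + affine, two ops each); bilinear resize = 11 x
    out_elements; module-level global average pooling = (window + 1) x
    out_elements; biases, activations and elementwise gating = 0. Inside the
    backbone only the batch-norm terms are counted: the published totals were
    produced by a module-hook profiler that does not see the reference
    implementation's custom same-padded convolution class, and the numbers
    are reproducible only under that convention. The backbone's vestigial
    1280-channel head contributes parameters but no MACs (never executed).

``full``
    Counts every convolution and pooling reduction in the executed graph
    under the same per-op rules — the physically meaningful cost.

Parameters are convention-free: the count is the sum over allocated trainable
tensors (including the vestigial head, which the published totals contain).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import (CBAMAttention, ECAAttention, GAMAttention,
                        NoAttention, SEAttention, SimAMAttention,
                        TAMAttention)
from .backbone import EfficientNetB1, MBConv, SqueezeExciteGate
from .model import ILWDeepLab
from .neck import ASPP, CWASPP, SeparableConv, _ImagePool
from .nn import (BatchNorm2d, BilinearResize, Conv2d, GlobalAvgPool, Identity,
                 Module, ReLU, Sequential, Sigmoid, SiLU)


@dataclass
class Convention:
    name: str = "published"
    bn_factor: int = 4
    bilinear_factor: int = 11
    pool_plus_one: bool = True
    count_bias: bool = False
    count_backbone_convs: bool = False
    count_backbone_pools: bool = False

    @classmethod
    def published(cls) -> "Convention":
        return cls()

    @classmethod
    def full(cls) -> "Convention":
        return cls(name="full", count_backbone_convs=True,
                   count_backbone_pools=True)


@dataclass
class LayerEntry:
    name: str
    params: int
    macs: int


@dataclass
class ComplexityReport:
    parameters: int
    macs: int
    input_side: int
    convention: Convention
    per_layer: list[LayerEntry] = field(default_factory=list)

    @property
    def macs_millions(self) -> float:
        return self.macs / 1e6

    @property
    def macs_billions(self) -> float:
        return self.macs / 1e9

    @property
    def parameters_millions(self) -> float:
        return self.parameters / 1e6


def count_parameters(model: Module) -> int:
    """Sum of trainable tensor element counts (independent of input size)."""
    return model.num_parameters()


class _Walker:
    def __init__(self, conv: Convention):
        self.conv = conv
        self.entries: list[LayerEntry] = []
        self.in_backbone = False

    def add(self, name: str, params: int, macs: int) -> None:
        self.entries.append(LayerEntry(name, int(params), int(macs)))

    # returns (channels, hw) after the module
    def walk(self, m: Module, name: str, c: int, hw: int) -> tuple[int, int]:
        cv = self.conv
        if isinstance(m, Conv2d):
            hw_out = -(-hw // m.stride)
            counted = cv.count_backbone_convs if self.in_backbone else True
            macs = 0
            if counted:
                macs = m.cout * hw_out * hw_out * (m.cin // m.groups) * m.k * m.k
                if cv.count_bias and m.bias is not None:
                    macs += m.cout * hw_out * hw_out
            self.add(name, m.num_parameters(), macs)
            return m.cout, hw_out
        if isinstance(m, BatchNorm2d):
            self.add(name, m.num_parameters(), cv.bn_factor * c * hw * hw)
            return c, hw
        if isinstance(m, (ReLU, SiLU, Sigmoid, Identity, NoAttention)):
            return c, hw
        if isinstance(m, GlobalAvgPool):
            counted = cv.count_backbone_pools if self.in_backbone else True
            k = hw * hw + (1 if cv.pool_plus_one else 0)
            self.add(name, 0, k * c if counted else 0)
            return c, 1
        if isinstance(m, BilinearResize):
            hw_out = hw * m.scale
            self.add(name, 0, cv.bilinear_factor * c * hw_out * hw_out)
            return c, hw_out
        if isinstance(m, Sequential):
            for i, sub in enumerate(m):
                c, hw = self.walk(sub, f"{name}.{i}", c, hw)
            return c, hw
        if isinstance(m, SeparableConv):
            c, hw = self.walk(m.depthwise, name + ".dw", c, hw)
            return self.walk(m.pointwise, name + ".pw", c, hw)
        if isinstance(m, _ImagePool):
            c2, _ = self.walk(m.pool, name + ".pool", c, hw)
            c2, _ = self.walk(m.conv, name + ".conv", c2, 1)
            if m.bn is not None:
                self.walk(m.bn, name + ".bn", c2, 1)
            return c2, hw          # broadcast back to the grid
        if isinstance(m, SqueezeExciteGate):
            ce, _ = self.walk(m.pool, name + ".pool", c, hw)
            cs, _ = self.walk(m.fc1, name + ".fc1", ce, 1)
            self.walk(m.fc2, name + ".fc2", cs, 1)
            return c, hw
        if isinstance(m, MBConv):
            if m.expand is not None:
                c, hw = self.walk(m.expand, name + ".expand", c, hw)
            c, hw = self.walk(m.dw, name + ".dw", c, hw)
            c, hw = self.walk(m.se, name + ".se", c, hw)
            c, hw = self.walk(m.project, name + ".project", c, hw)
            return c, hw
        if isinstance(m, EfficientNetB1):
            self.in_backbone = True
            c, hw = self.walk(m.stem, name + ".stem", c, hw)
            for i, blk in enumerate(m.blocks):
                c, hw = self.walk(blk, f"{name}.block{i}", c, hw)
            if m.vestigial_head is not None:
                self.add(name + ".vestigial_head",
                         m.vestigial_head.num_parameters(), 0)
            self.in_backbone = False
            return c, hw
        if isinstance(m, CWASPP):
            cr, _ = self.walk(m.reduce, name + ".reduce", c, hw)
            ci = cr
            for i, st in enumerate(m.stages):
                ci, _ = self.walk(st, f"{name}.stage{i}", ci, hw)
            if m.image_pool is not None:
                self.walk(m.image_pool, name + ".image_pool", c, hw)
            c2, _ = self.walk(m.project, name + ".project", m.concat_channels, hw)
            self.walk(m.project_bn, name + ".project_bn", c2, hw)
            return c2, hw
        if isinstance(m, ASPP):
            self.walk(m.branch0, name + ".branch0", c, hw)
            for i, b in enumerate(m.branches):
                self.walk(b, f"{name}.branch{i + 1}", c, hw)
            if m.cfg.include_image_pooling:
                self.walk(m.image_pool, name + ".image_pool", c, hw)
            cat = m.project.cin
            c2, _ = self.walk(m.project, name + ".project", cat, hw)
            self.walk(m.project_bn, name + ".project_bn", c2, hw)
            return c2, hw
        if isinstance(m, SEAttention):
            self.walk(m.pool, name + ".pool", c, hw)
            cs, _ = self.walk(m.fc1, name + ".fc1", c, 1)
            self.walk(m.fc2, name + ".fc2", cs, 1)
            return c, hw
        if isinstance(m, CBAMAttention):
            k = hw * hw + (1 if self.conv.pool_plus_one else 0)
            self.add(name + ".avgpool", 0, k * c)   # max pool costs 0
            cs = m.fc1.cout
            self.add(name + ".mlp", m.fc1.num_parameters() + m.fc2.num_parameters(),
                     2 * 2 * c * cs)                # shared MLP, two passes
            self.walk(m.spatial, name + ".spatial", 2, hw)
            return c, hw
        if isinstance(m, ECAAttention):
            k = hw * hw + (1 if self.conv.pool_plus_one else 0)
            self.add(name + ".pool", 0, k * c)
            self.add(name + ".conv1d", m.weight.numel(), m.k * c)
            return c, hw
        if isinstance(m, GAMAttention):
            cs, _ = self.walk(m.fc1, name + ".fc1", c, hw)
            self.walk(m.fc2, name + ".fc2", cs, hw)
            self.walk(m.spatial_bn, name + ".spatial_bn", 2, hw)
            self.walk(m.spatial, name + ".spatial", 2, hw)
            return c, hw
        if isinstance(m, SimAMAttention):
            return c, hw
        if isinstance(m, TAMAttention):
            # rotated 2-channel maps have c*hw locations each
            loc = c * hw
            for i, (cv_, bn) in enumerate(((m.conv1, m.bn1), (m.conv2, m.bn2))):
                self.add(f"{name}.branch{i}.conv", cv_.num_parameters(),
                         2 * cv_.k * cv_.k * loc)
                self.add(f"{name}.branch{i}.bn", bn.num_parameters(),
                         self.conv.bn_factor * loc)
            return c, hw
        if isinstance(m, ILWDeepLab):
            c, hw = self.walk(m.backbone, "backbone", 3, hw)
            c, hw = self.walk(m.neck, "neck", c, hw)
            c, hw = self.walk(m.attention, "attention", c, hw)
            c, hw = self.walk(m.refine, "refine", c, hw)
            c, hw = self.walk(m.up_dec, "decoder.up", c, hw)
            cl, _ = self.walk(m.low_reduce, "decoder.low_reduce",
                              m.low_reduce.layers[0].cin, hw)
            c, hw = self.walk(m.fuse, "decoder.fuse", c + cl, hw)
            c, hw = self.walk(m.classifier, "classifier", c, hw)
            return self.walk(m.up_out, "classifier.up", c, hw)
        raise TypeError(f"profiler does not know {type(m).__name__}")


def count_macs(model: Module, input_side: int = 512,
               convention: Convention | str = "published",
               in_channels: int = 3) -> int:
    if input_side % 16:
        raise ValueError("input side must be divisible by 16")
    if isinstance(convention, str):
        convention = (Convention.published() if convention == "published"
                      else Convention.full())
    w = _Walker(convention)
    w.walk(model, type(model).__name__.lower(), in_channels, input_side)
    return sum(e.macs for e in w.entries)


def profile(model: Module, input_side: int = 512,
            convention: Convention | str = "published",
            in_channels: int = 3) -> ComplexityReport:
    if isinstance(convention, str):
        convention = (Convention.published() if convention == "published"
                      else Convention.full())
    w = _Walker(convention)
    w.walk(model, type(model).__name__.lower(), in_channels, input_side)
    macs = sum(e.macs for e in w.entries)
    return ComplexityReport(parameters=count_parameters(model), macs=macs,
                            input_side=input_side, convention=convention,
                            per_layer=w.entries)


@dataclass
class ParetoPoint:
    label: str
    params: float
    macs: float
    miou: float

    def __post_init__(self):
        if not all(np.isfinite([self.params, self.macs, self.miou])):
            raise ValueError("pareto point fields must be finite")


def _dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    """a dominates b under (params down, macs down, miou up)."""
    no_worse = (a.params <= b.params and a.macs <= b.macs
                and a.miou >= b.miou)
    strictly = (a.params < b.params or a.macs < b.macs or a.miou > b.miou)
    return no_worse and strictly


def pareto_front(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Order-stable subset of non-dominated points."""
    if not points:
        raise ValueError("need at least one point")
    return [p for p in points
            if not any(_dominates(q, p) for q in points if q is not p)]
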