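"""Encoder-head attention registry with exact parameter contracts.

Each mechanism operates on the 256-channel neck output and is shape
preserving. The parameter counts are hard contracts (asserted at build time)
that reproduce the published cost deltas of the attention comparison:

    none 0 | se 8192 | cbam 8290 | eca 5 | gam 32870 | simam 0 | tam 200

The squeeze-and-excitation gate (the mechanism the final model adopts) also
implements a backward pass so the full network can be trained; the remaining
mechanisms are provided for comparison and complexity profiling (forward /
evaluation only).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Module, Parameter, ReLU,
                 Sigmoid)

ATTENTION_KINDS = ("none", "se", "cbam", "eca", "gam", "simam", "tam")

PARAM_CONTRACTS = {"none": 0, "se": 8192, "cbam": 8290, "eca": 5,
                   "gam": 32870, "simam": 0, "tam": 200}


@dataclass
class AttentionSpec:
    kind: str = "se"
    channels: int = 256
    reduction: int = 16          # se / cbam bottleneck ratio
    gam_reduction: int = 4       # gam channel bottleneck ratio
    spatial_kernel: int = 7      # cbam / gam / tam spatial gate kernel
    eca_kernel: int = 5          # adaptive 1-D kernel at 256 channels
    simam_lambda: float = 1e-4

    def __post_init__(self):
        if self.kind not in ATTENTION_KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.channels != 256:
            raise ValueError("attention operates on the 256-channel neck output")


class NoAttention(Module):
    def forward(self, x, training: bool = False):
        return x

    def backward(self, grad):
        return grad


class SEAttention(Module):
    """Squeeze-and-excitation: pool -> bias-free two-layer bottleneck -> sigmoid gate."""

    def __init__(self, spec: AttentionSpec, rng):
        super().__init__()
        c, r = spec.channels, spec.reduction
        self.pool = GlobalAvgPool()
        self.fc1 = Conv2d(c, c // r, 1, bias=False, rng=rng)
        self.act = ReLU()
        self.fc2 = Conv2d(c // r, c, 1, bias=False, rng=rng)
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
        return gx + self.pool.backward(gs)


def _channel_pool(x: np.ndarray) -> np.ndarray:
    """Stack per-pixel mean and max over channels -> (N,2,H,W)."""
    return np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)


class CBAMAttention(Module):
    """Channel gate (shared bias-free MLP over avg+max pooled vectors) then
    spatial gate (7x7 conv over the 2-channel pooled map)."""

    def __init__(self, spec: AttentionSpec, rng):
        super().__init__()
        c, r = spec.channels, spec.reduction
        self.fc1 = Conv2d(c, c // r, 1, bias=False, rng=rng)
        self.fc2 = Conv2d(c // r, c, 1, bias=False, rng=rng)
        self.relu = ReLU()
        self.spatial = Conv2d(2, 1, spec.spatial_kernel, bias=False, rng=rng)

    def forward(self, x, training: bool = False):
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        att = 0.0
        for s in (avg, mx):
            att = att + self.fc2.forward(
                self.relu.forward(self.fc1.forward(s, training), training),
                training)
        x = x * _sigmoid(att)
        sp = self.spatial.forward(_channel_pool(x), training)
        return x * _sigmoid(sp)

    def backward(self, grad):
        raise NotImplementedError(
            "cbam is provided for evaluation/profiling; train with 'se'")


class ECAAttention(Module):
    """Efficient channel attention: 1-D convolution across pooled channels."""

    def __init__(self, spec: AttentionSpec, rng):
        super().__init__()
        self.k = spec.eca_kernel
        self.weight = Parameter(
            rng.normal(0, 0.1, size=self.k).astype(np.float32))

    def forward(self, x, training: bool = False):
        s = x.mean(axis=(2, 3))                       # (N, C)
        pad = self.k // 2
        sp = np.pad(s, ((0, 0), (pad, pad)), mode="edge")
        att = np.zeros_like(s)
        for i in range(self.k):
            att += self.weight.data[i] * sp[:, i:i + s.shape[1]]
        return x * _sigmoid(att)[:, :, None, None]

    def backward(self, grad):
        raise NotImplementedError(
            "eca is provided for evaluation/profiling; train with 'se'")


class GAMAttention(Module):
    """Global attention: per-pixel channel MLP gate, then a compact spatial
    gate (BN over the 2-channel pooled map + 7x7 conv)."""

    def __init__(self, spec: AttentionSpec, rng):
        super().__init__()
        c, r = spec.channels, spec.gam_reduction
        self.fc1 = Conv2d(c, c // r, 1, bias=False, rng=rng)
        self.relu = ReLU()
        self.fc2 = Conv2d(c // r, c, 1, bias=False, rng=rng)
        self.spatial_bn = BatchNorm2d(2)
        self.spatial = Conv2d(2, 1, spec.spatial_kernel, bias=False, rng=rng)

    def forward(self, x, training: bool = False):
        att = self.fc2.forward(
            self.relu.forward(self.fc1.forward(x, training), training),
            training)
        x = x * _sigmoid(att)
        sp = self.spatial_bn.forward(_channel_pool(x), training)
        sp = self.spatial.forward(sp, training)
        return x * _sigmoid(sp)

    def backward(self, grad):
        raise NotImplementedError(
            "gam is provided for evaluation/profiling; train with 'se'")


class SimAMAttention(Module):
    """Parameter-free energy-based attention (lambda-stabilised)."""

    def __init__(self, spec: AttentionSpec, rng=None):
        super().__init__()
        self.lam = spec.simam_lambda

    def forward(self, x, training: bool = False):
        n = x.shape[2] * x.shape[3] - 1
        d = x - x.mean(axis=(2, 3), keepdims=True)
        v = (d ** 2).sum(axis=(2, 3), keepdims=True) / n
        e_inv = d ** 2 / (4 * (v + self.lam)) + 0.5
        return x * _sigmoid(e_inv)

    def backward(self, grad):
        raise NotImplementedError(
            "simam is provided for evaluation/profiling; train with 'se'")


class TAMAttention(Module):
    """Triplet-style rotated attention (two cross-dimension branches, no
    spatial branch): each branch pools to a 2-channel map over a rotated view
    and gates through BN + a 7x7 convolution."""

    def __init__(self, spec: AttentionSpec, rng):
        super().__init__()
        k = spec.spatial_kernel
        self.conv1 = Conv2d(2, 1, k, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(1)
        self.conv2 = Conv2d(2, 1, k, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(1)

    def _branch(self, xr, conv, bn, training):
        z = _channel_pool(xr)
        g = bn.forward(conv.forward(z, training), training)
        return xr * _sigmoid(g)

    def forward(self, x, training: bool = False):
        # branch 1: rotate so H plays the channel role -> gate over (C, W)
        x1 = self._branch(x.transpose(0, 2, 1, 3), self.conv1, self.bn1,
                          training).transpose(0, 2, 1, 3)
        # branch 2: rotate so W plays the channel role -> gate over (H, C)
        x2 = self._branch(x.transpose(0, 3, 2, 1), self.conv2, self.bn2,
                          training).transpose(0, 3, 2, 1)
        return 0.5 * (x1 + x2)

    def backward(self, grad):
        raise NotImplementedError(
            "tam is provided for evaluation/profiling; train with 'se'")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


_BUILDERS = {"none": lambda s, r: NoAttention(), "se": SEAttention,
             "cbam": CBAMAttention, "eca": ECAAttention, "gam": GAMAttention,
             "simam": SimAMAttention, "tam": TAMAttention}


def build_attention(spec: AttentionSpec, rng=None) -> Module:
    """Build a block and verify its parameter-count contract."""
    rng = rng or np.random.default_rng(0)
    builder = _BUILDERS[spec.kind]
    block = builder(spec, rng) if spec.kind != "none" else NoAttention()
    got = block.num_parameters()
    want = PARAM_CONTRACTS[spec.kind]
    if got != want:
        raise AssertionError(
            f"{spec.kind}: parameter contract violated ({got} != {want})")
    return block


def attention_param_contract(kind: str) -> int:
    return PARAM_CONTRACTS[kind]
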