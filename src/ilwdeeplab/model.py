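"""Assembly of the lightweight encoder–decoder segmentation network.

Graph: backbone -> neck (waterfall or parallel atrous pooling, which ends in
a 1x1 projection to 256 channels) -> channel attention -> separable 3x3
refinement -> bilinear x4 upsampling -> concatenation with the 1x1-reduced
low-level map (24 -> 48 channels) -> separable 3x3 fusion -> 1x1 classifier
-> bilinear x4 upsampling back to input resolution.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import AttentionSpec, build_attention
from .backbone import (BackboneSpec, EfficientNetB1, LOW_LEVEL_CHANNELS)
from .neck import (ASPP, CWASPP, NeckConfig, SeparableConv,
                   aspp_default_config)
from .nn import (BatchNorm2d, BilinearResize, Conv2d, Module, ReLU, Sequential)


@dataclass
class ModelConfig:
    num_classes: int = 103
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    neck: NeckConfig = field(default_factory=NeckConfig)
    attention: AttentionSpec = field(default_factory=lambda: AttentionSpec("se"))
    low_level_channels_reduced: int = 48
    fuse_channels: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes (background + food)")


def lw_config(num_classes: int = 103, seed: int = 0) -> ModelConfig:
    """Lightweight model: waterfall neck, no head attention."""
    return ModelConfig(num_classes=num_classes,
                       attention=AttentionSpec("none"), seed=seed)


def ilw_config(num_classes: int = 103, attention: str = "se",
               seed: int = 0) -> ModelConfig:
    """Improved lightweight model: waterfall neck + head attention."""
    return ModelConfig(num_classes=num_classes,
                       attention=AttentionSpec(attention), seed=seed)


def baseline_aspp_config(num_classes: int = 103, seed: int = 0) -> ModelConfig:
    """Reference assembly with the standard parallel ASPP neck."""
    return ModelConfig(num_classes=num_classes, neck=aspp_default_config(),
                       attention=AttentionSpec("none"), seed=seed)


class ILWDeepLab(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = EfficientNetB1(cfg.backbone, seed=cfg.seed)
        if cfg.neck.mode == "cwaspp":
            self.neck = CWASPP(cfg.neck, rng=rng)
        else:
            self.neck = ASPP(cfg.neck, rng=rng)
        self.attention = build_attention(cfg.attention, rng=rng)
        c = cfg.neck.out_channels
        self.refine = Sequential(SeparableConv(c, c, 3, rng=rng),
                                 BatchNorm2d(c), ReLU())
        self.up_dec = BilinearResize(4)
        self.low_reduce = Sequential(
            Conv2d(LOW_LEVEL_CHANNELS, cfg.low_level_channels_reduced, 1,
                   bias=False, rng=rng),
            BatchNorm2d(cfg.low_level_channels_reduced), ReLU())
        fuse_in = c + cfg.low_level_channels_reduced
        self.fuse = Sequential(SeparableConv(fuse_in, cfg.fuse_channels, 3,
                                             rng=rng),
                               BatchNorm2d(cfg.fuse_channels), ReLU())
        self.classifier = Conv2d(cfg.fuse_channels, cfg.num_classes, 1,
                                 bias=True, rng=rng)
        self.up_out = BilinearResize(4)
        self._low_ch = None

    def forward(self, x, training: bool = False):
        feats = self.backbone.forward(x, training)
        h = self.neck.forward(feats.high, training)
        h = self.attention.forward(h, training)
        h = self.refine.forward(h, training)
        h = self.up_dec.forward(h, training)
        low = self.low_reduce.forward(feats.low, training)
        self._low_ch = low.shape[1]
        cat = np.concatenate([h, low], axis=1)
        f = self.fuse.forward(cat, training)
        logits = self.classifier.forward(f, training)
        return self.up_out.forward(logits, training)

    def backward(self, grad):
        g = self.up_out.backward(grad)
        g = self.classifier.backward(g)
        g = self.fuse.backward(g)
        c = g.shape[1] - self._low_ch
        gh, glow = g[:, :c], g[:, c:]
        glow = self.low_reduce.backward(glow)
        gh = self.up_dec.backward(gh)
        gh = self.refine.backward(gh)
        gh = self.attention.backward(gh)
        gh = self.neck.backward(gh)
        return self.backbone.backward(glow, gh)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        state = {k: v for k, v in self.state_dict().items()}
        cfg = asdict(self.cfg)
        np.savez_compressed(path, __config__=json.dumps(cfg), **state)

    @classmethod
    def load(cls, path: str) -> "ILWDeepLab":
        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["__config__"]))
            cfg = ModelConfig(
                num_classes=cfg_d["num_classes"],
                backbone=BackboneSpec(**cfg_d["backbone"]),
                neck=NeckConfig(**{k: tuple(v) if k == "rates" else v
                                   for k, v in cfg_d["neck"].items()}),
                attention=AttentionSpec(**cfg_d["attention"]),
                low_level_channels_reduced=cfg_d["low_level_channels_reduced"],
                fuse_channels=cfg_d["fuse_channels"], seed=cfg_d["seed"])
            model = cls(cfg)
            model.load_state_dict({k: z[k] for k in z.files
                                   if k != "__config__"})
        return model


def build_model(cfg: ModelConfig) -> ILWDeepLab:
    return ILWDeepLab(cfg)


def predict_labels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the class axis; ties break to the smaller id.

    Accepts (K, H, W) or (N, K, H, W) logits.
    """
    if not np.isfinite(logits).all():
        raise ValueError("logits contain NaN or infinity")
    axis = 0 if logits.ndim == 3 else 1
    return logits.argmax(axis=axis)


def softmax_probs(logits: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Numerically stable softmax over the class axis."""
    if axis is None:
        axis = 0 if logits.ndim == 3 else 1
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
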