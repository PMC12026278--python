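"""Scikit-learn-style estimator facade over the segmentation network.

``ILWSegmenter`` behaves like a classifier over pixels: ``fit`` takes a batch
of RGB images with per-pixel integer labels, ``predict`` returns label maps,
``predict_proba`` softmax stacks, and ``score`` the per-image mean IoU. It
composes with sklearn model-selection utilities through
``get_params``/``set_params`` (inherited from ``BaseEstimator``).
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import ILWDeepLab, ModelConfig, predict_labels, softmax_probs
from .attention import AttentionSpec
from .neck import NeckConfig, aspp_default_config
from .train import TrainConfig, mean_iou, train_arrays


def _as_nchw(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("X must be (n_samples, height, width, 3)")
    if X.shape[1] % 16 or X.shape[2] % 16:
        raise ValueError("image sides must be divisible by 16")
    X = X.astype(np.float32)
    if X.max() > 1.5:          # 8-bit input
        X = X / 255.0
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


class ILWSegmenter(BaseEstimator):
    """Lightweight encoder–decoder semantic segmenter.

    Parameters mirror the training recipe; ``attention`` selects the
    encoder-head mechanism ("se" is the published choice; only "se"/"none"
    support training) and ``neck`` the multi-scale module ("cwaspp" or
    "aspp").
    """

    def __init__(self, num_classes: int | None = None, attention: str = "se",
                 neck: str = "cwaspp", epochs: int = 30, batch_size: int = 8,
                 base_lr: float = 0.05, momentum: float = 0.9,
                 weight_decay: float = 1e-4, poly_power: float = 0.9,
                 seed: int = 0):
        self.num_classes = num_classes
        self.attention = attention
        self.neck = neck
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.poly_power = poly_power
        self.seed = seed

    # -- sklearn protocol ----------------------------------------------------
    def fit(self, X, y):
        Xc = _as_nchw(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (Xc.shape[0],) + Xc.shape[2:]:
            raise ValueError("y must be (n_samples, height, width)")
        k = self.num_classes or int(y.max()) + 1
        if y.min() < 0 or y.max() >= k:
            raise ValueError("labels outside 0..num_classes-1")
        cfg = ModelConfig(
            num_classes=k,
            neck=(NeckConfig() if self.neck == "cwaspp"
                  else aspp_default_config()),
            attention=AttentionSpec(self.attention), seed=self.seed)
        self.model_ = ILWDeepLab(cfg)
        tc = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                         base_lr=self.base_lr, momentum=self.momentum,
                         weight_decay=self.weight_decay,
                         poly_power=self.poly_power, seed=self.seed,
                         input_side=Xc.shape[-1])
        res = train_arrays(self.model_, Xc, y, tc)
        self.loss_trace_ = res.loss_trace
        self.classes_ = np.arange(k)
        self.n_classes_ = k
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_labels(self.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return softmax_probs(self.decision_function(X), axis=1)

    def decision_function(self, X) -> np.ndarray:
        """Raw per-pixel logits (n, K, H, W)."""
        self._check_fitted()
        Xc = _as_nchw(X)
        outs = [self.model_.forward(Xc[i:i + self.batch_size], training=False)
                for i in range(0, len(Xc), self.batch_size)]
        return np.concatenate(outs)

    def score(self, X, y) -> float:
        """Per-image mean IoU (empty-union classes skipped)."""
        pred = self.predict(X)
        return mean_iou(np.asarray(y), pred, self.n_classes_).miou
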