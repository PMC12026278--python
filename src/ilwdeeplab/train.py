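"""Training recipe and the per-image mean-IoU metric.

Optimisation follows the reference recipe: SGD (momentum 0.9, weight decay
1e-4), cross-entropy over all pixels, batch size 8, and a polynomial
learning-rate decay applied after every iteration,
``lr = base_lr * (1 - t / T)^0.9``, reaching zero when training completes.

The metric averages per-class IoU within each image and then across images.
Classes whose union is empty in an image contribute nothing to that image's
average by default ("skip"); the alternative conventions (count as 1 or as 0)
are selectable for comparability with other codebases.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ClassPalette, DatasetManifest, load_sample, preprocess
from .model import ILWDeepLab, predict_labels
from .nn import SGD


def poly_lr(iteration: int, max_iterations: int, base_lr: float,
            power: float = 0.9) -> float:
    """Polynomial decay: base_lr * (1 - t/T)^power; exactly 0 at t = T."""
    if max_iterations <= 0:
        raise ValueError("max_iterations must be positive")
    if not 0 <= iteration <= max_iterations:
        raise ValueError("iteration outside [0, max_iterations]")
    return float(base_lr * (1.0 - iteration / max_iterations) ** power)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    base_lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    seed: int = 0
    input_side: int = 512
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.base_lr <= 0 or self.poly_power <= 0:
            raise ValueError("base_lr and poly_power must be positive")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits."""
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    picked = p[idx_n, labels, idx_h, idx_w]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    grad = p.copy()
    grad[idx_n, labels, idx_h, idx_w] -= 1.0
    grad /= n * h * w
    return loss, grad.astype(np.float32)


@dataclass
class TrainResult:
    loss_trace: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)

    @property
    def initial_loss(self) -> float:
        return self.loss_trace[0]

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def _load_split(manifest: DatasetManifest, palette: ClassPalette):
    if not manifest.items:
        raise ValueError("manifest is empty")
    return [load_sample(img, msk, palette) for img, msk in manifest.items]


def train_arrays(model: ILWDeepLab, images: np.ndarray, labels: np.ndarray,
                 cfg: TrainConfig) -> TrainResult:
    """Core loop over in-memory arrays (images NCHW in [0,1], labels NHW).

    One seeded generator drives shuffling and the per-sample horizontal-flip
    augmentation; the schedule decays after every iteration.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = math.ceil(n / cfg.batch_size)
    max_iter = cfg.epochs * steps_per_epoch
    opt = SGD(model.parameters(), lr=cfg.base_lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    result = TrainResult()
    it = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            batch = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            x = images[batch].copy()
            y = labels[batch].copy()
            flip = rng.random(len(batch)) < 0.5
            x[flip] = x[flip][:, :, :, ::-1]
            y[flip] = y[flip][:, :, ::-1]
            lr = poly_lr(it, max_iter, cfg.base_lr, cfg.poly_power)
            opt.lr = lr
            logits = model.forward(np.ascontiguousarray(x), training=True)
            loss, grad = cross_entropy(logits, np.ascontiguousarray(y))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at iteration {it} (lr={lr:.2e})")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            result.loss_trace.append(loss)
            result.lr_trace.append(lr)
            it += 1
    return result


def train(model: ILWDeepLab, manifest: DatasetManifest,
          cfg: TrainConfig, palette: ClassPalette) -> TrainResult:
    """Run the full recipe on a manifest; reproducible from cfg.seed."""
    samples = _load_split(manifest, palette)
    ims, labs = zip(*(preprocess(s, cfg.input_side, training=False)
                      for s in samples))
    return train_arrays(model, np.stack(ims), np.stack(labs), cfg)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------
@dataclass
class EvalResult:
    miou: float
    per_image_class_iou: np.ndarray     # (N, K) with NaN where skipped
    n_images: int
    num_classes: int


def mean_iou(gt: np.ndarray, pred: np.ndarray, num_classes: int,
             empty_union: str = "skip") -> EvalResult:
    """Per-image, per-class intersection over union, averaged per image and
    then over images.

    ``empty_union`` decides what a class with no ground-truth and no predicted
    pixels contributes to its image's average: "skip" (excluded), "one", or
    "zero".
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.ndim == 2:
        gt, pred = gt[None], pred[None]
    if gt.shape != pred.shape:
        raise ValueError("gt and pred shapes differ")
    if gt.shape[0] == 0:
        raise ValueError("no images")
    if empty_union not in ("skip", "one", "zero"):
        raise ValueError("empty_union must be skip|one|zero")
    n = gt.shape[0]
    table = np.full((n, num_classes), np.nan)
    for i in range(n):
        for k in range(num_classes):
            g = gt[i] == k
            p = pred[i] == k
            union = np.logical_or(g, p).sum()
            if union == 0:
                if empty_union == "one":
                    table[i, k] = 1.0
                elif empty_union == "zero":
                    table[i, k] = 0.0
                continue
            table[i, k] = np.logical_and(g, p).sum() / union
    per_image = np.nanmean(table, axis=1)
    return EvalResult(float(per_image.mean()), table, n, num_classes)


def evaluate(model: ILWDeepLab, manifest: DatasetManifest,
             palette: ClassPalette, input_side: int = 512,
             batch_size: int = 8, empty_union: str = "skip") -> EvalResult:
    """Deterministic evaluation-mode mIoU over a manifest."""
    samples = _load_split(manifest, palette)
    gts, preds = [], []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        ims, labs = zip(*(preprocess(s, input_side, training=False)
                          for s in chunk))
        logits = model.forward(np.stack(ims), training=False)
        preds.append(predict_labels(logits))
        gts.append(np.stack(labs))
    return mean_iou(np.concatenate(gts), np.concatenate(preds),
                    manifest.num_classes, empty_union)
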