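"""Post hoc conformal uncertainty for segmentation.

The softmax output is read as a multi-label mask: a pixel keeps every class
whose score exceeds the threshold lambda-hat = 1 - lambda (coverage
parameter lambda). Counting the selected labels per pixel (NL) and dividing
each selected indicator by that count yields the per-class uncertainty stack
V with values in [0, 1]; V sums to one over classes wherever at least one
label is selected. A pixel's scalar uncertainty is summarised as
u = 1 - 1/NL (0 for a confident single label), with u = 1 for the empty
selection — a convention for a case the default threshold never produces.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LAMBDA_HAT = 0.01
CALIBRATION_GRID = np.logspace(-4, np.log10(0.5), 100)


@dataclass
class MultiLabelMask:
    mask: np.ndarray          # (K, H, W) in {0, 1}
    lambda_hat: float

    @property
    def coverage_lambda(self) -> float:
        return 1.0 - self.lambda_hat


@dataclass
class LabelCountMap:
    counts: np.ndarray        # (H, W) integers in 0..K


@dataclass
class UncertaintyHeatmap:
    stack: np.ndarray         # (K, H, W) in [0, 1]
    summary: np.ndarray       # (H, W) in [0, 1]; 1 - 1/NL, 1 where NL == 0


def _check_probs(probs: np.ndarray) -> None:
    if probs.ndim != 3:
        raise ValueError("expected a (K, H, W) softmax stack")
    if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
        raise ValueError("probabilities outside [0, 1]")
    sums = probs.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("per-pixel probabilities must sum to 1")


def threshold_softmax(probs: np.ndarray, lambda_hat: float = DEFAULT_LAMBDA_HAT
                      ) -> MultiLabelMask:
    """Select every label with softmax score strictly above lambda-hat."""
    _check_probs(probs)
    if not 0.0 <= lambda_hat <= 1.0:
        raise ValueError("lambda_hat must lie in [0, 1]")
    return MultiLabelMask((probs > lambda_hat).astype(np.uint8), lambda_hat)


def count_labels(mask: MultiLabelMask) -> LabelCountMap:
    return LabelCountMap(mask.mask.sum(axis=0).astype(np.int64))


def variasco(mask: MultiLabelMask,
             counts: LabelCountMap | None = None) -> UncertaintyHeatmap:
    """V[k, i, j] = mask[k, i, j] / NL[i, j] (0 where NL == 0)."""
    if counts is None:
        counts = count_labels(mask)
    nl = counts.counts
    if nl.shape != mask.mask.shape[1:]:
        raise ValueError("count map shape does not match mask")
    safe = np.maximum(nl, 1)
    stack = mask.mask.astype(np.float64) / safe[None]
    summary = np.where(nl > 0, 1.0 - 1.0 / safe, 1.0)
    return UncertaintyHeatmap(stack, summary)


def calibrate_lambda(cal_probs: list[np.ndarray], cal_labels: list[np.ndarray],
                     target_coverage: float = 0.95,
                     grid: np.ndarray = CALIBRATION_GRID) -> float:
    """Largest grid threshold whose selection still covers the true label of
    at least ``target_coverage`` of the calibration pixels.

    With no calibration data (empty call sites use the default directly),
    the empirical default threshold is 0.01.
    """
    if not 0.0 < target_coverage < 1.0:
        raise ValueError("target_coverage must lie in (0, 1)")
    if not cal_probs:
        raise ValueError("calibration set is empty")
    if len(cal_probs) != len(cal_labels):
        raise ValueError("probs and labels differ in length")
    # score of the true label at each pixel
    true_scores = []
    for probs, labels in zip(cal_probs, cal_labels):
        _check_probs(probs)
        h, w = labels.shape
        idx_h, idx_w = np.ogrid[:h, :w]
        true_scores.append(probs[labels, idx_h, idx_w].ravel())
    scores = np.concatenate(true_scores)
    best = None
    for lam in sorted(grid):
        coverage = float((scores > lam).mean())
        if coverage >= target_coverage:
            best = float(lam)
        else:
            break
    if best is None:
        raise ValueError("no grid threshold achieves the requested coverage")
    return best


def conformal_stack(probs: np.ndarray,
                    lambda_hat: float = DEFAULT_LAMBDA_HAT
                    ) -> tuple[MultiLabelMask, LabelCountMap, UncertaintyHeatmap]:
    """Convenience chain: threshold -> counts -> heatmap."""
    mask = threshold_softmax(probs, lambda_hat)
    counts = count_labels(mask)
    return mask, counts, variasco(mask, counts)
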