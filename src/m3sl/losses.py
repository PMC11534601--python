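"""Training losses: soft Dice (F-beta) loss plus binary focal loss.

Lesion voxels are a tiny minority of a FLAIR volume (true-negative fraction
around 0.98), so the training objective combines two imbalance-aware terms:

* a soft Dice loss, 1 minus the F-beta overlap score with soft counts
  TP = sum(p*g), FP = sum(p*(1-g)), FN = sum((1-p)*g);
* a binary focal loss, cross-entropy with the easy-example down-weighting
  factor (1-PT)^gamma and class weight alpha:

      FL = -GT * alpha * (1-PT)^gamma * log(PT)
           - (1-GT) * alpha * PT^gamma * log(1-PT)

  averaged over voxels.

The total objective is their unweighted sum.  Analytic gradients with
respect to the predicted probabilities are provided for the NumPy training
loop.
"""
from __future__ import annotations

import warnings

import numpy as np

from .errors import ShapeError, UndefinedMetricError

DEFAULT_SMOOTH = 1e-6
PROB_EPS = 1e-7


def dice_score(tp: float, fp: float, fn: float, beta: float = 1.0) -> float:
    """F-beta overlap score from hard voxel counts.

        (1 + beta^2) * TP / ((1 + beta^2) * TP + beta^2 * FN + FP)

    At beta = 1 this is the F-measure (harmonic mean of precision and
    recall); beta > 1 weighs recall more heavily.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError(f"counts must be non-negative, got tp={tp} fp={fp} fn={fn}")
    if tp == 0 and fp == 0 and fn == 0:
        raise UndefinedMetricError(
            "dice_score undefined when tp = fp = fn = 0 (no foreground anywhere)"
        )
    b2 = beta * beta
    return (1.0 + b2) * tp / ((1.0 + b2) * tp + b2 * fn + fp)


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ShapeError(f"pred shape {pred.shape} != gt shape {gt.shape}")


def soft_dice_loss(
    pred: np.ndarray,
    gt: np.ndarray,
    beta: float = 1.0,
    smooth: float = DEFAULT_SMOOTH,
) -> float:
    """1 - soft F-beta score, with a smoothing term in numerator and
    denominator; 0 (up to the smoothing perturbation) at a perfect binary
    prediction."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    _check_pair(pred, gt)
    b2 = beta * beta
    inter = float((pred * gt).sum())
    # denominator simplifies: (1+b2)*I + b2*(G - I) + (P - I) = b2*G + P
    num = (1.0 + b2) * inter + smooth
    den = b2 * float(gt.sum()) + float(pred.sum()) + smooth
    return 1.0 - num / den


def soft_dice_loss_grad(
    pred: np.ndarray,
    gt: np.ndarray,
    beta: float = 1.0,
    smooth: float = DEFAULT_SMOOTH,
) -> np.ndarray:
    """d(soft_dice_loss)/d(pred), elementwise."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    _check_pair(pred, gt)
    b2 = beta * beta
    inter = float((pred * gt).sum())
    num = (1.0 + b2) * inter + smooth
    den = b2 * float(gt.sum()) + float(pred.sum()) + smooth
    # loss = 1 - num/den; d num/d p_i = (1+b2)*g_i; d den/d p_i = 1
    return -((1.0 + b2) * gt * den - num) / (den * den)


def _clamp_probs(pt: np.ndarray) -> np.ndarray:
    if np.any(pt <= 0.0) or np.any(pt >= 1.0):
        warnings.warn(
            f"focal loss probabilities clamped to [{PROB_EPS}, 1-{PROB_EPS}]",
            RuntimeWarning,
            stacklevel=3,
        )
        pt = np.clip(pt, PROB_EPS, 1.0 - PROB_EPS)
    return pt


def focal_loss(
    gt: np.ndarray,
    pt: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> float:
    """Mean binary focal loss over voxels (both branches carry alpha)."""
    gt = np.asarray(gt, dtype=np.float64)
    pt = np.asarray(pt, dtype=np.float64)
    _check_pair(pt, gt)
    pt = _clamp_probs(pt)
    fg = -gt * alpha * (1.0 - pt) ** gamma * np.log(pt)
    bg = -(1.0 - gt) * alpha * pt**gamma * np.log1p(-pt)
    return float((fg + bg).mean())


def focal_loss_grad(
    gt: np.ndarray,
    pt: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> np.ndarray:
    """d(mean focal loss)/d(pt), elementwise."""
    gt = np.asarray(gt, dtype=np.float64)
    pt = np.asarray(pt, dtype=np.float64)
    _check_pair(pt, gt)
    pt = _clamp_probs(pt)
    one_m = 1.0 - pt
    if gamma == 0.0:
        d_fg = -1.0 / pt
        d_bg = 1.0 / one_m
    else:
        d_fg = gamma * one_m ** (gamma - 1.0) * np.log(pt) - one_m**gamma / pt
        d_bg = -gamma * pt ** (gamma - 1.0) * np.log1p(-pt) + pt**gamma / one_m
    g = alpha * (gt * d_fg + (1.0 - gt) * d_bg)
    return g / pt.size


def combined_loss(
    pred: np.ndarray,
    gt: np.ndarray,
    beta: float = 1.0,
    alpha: float = 0.25,
    gamma: float = 2.0,
    smooth: float = DEFAULT_SMOOTH,
) -> float:
    """Unweighted sum of soft Dice loss and focal loss."""
    return soft_dice_loss(pred, gt, beta, smooth) + focal_loss(gt, pred, alpha, gamma)


def combined_loss_grad(
    pred: np.ndarray,
    gt: np.ndarray,
    beta: float = 1.0,
    alpha: float = 0.25,
    gamma: float = 2.0,
    smooth: float = DEFAULT_SMOOTH,
) -> np.ndarray:
    return soft_dice_loss_grad(pred, gt, beta, smooth) + focal_loss_grad(
        gt, pred, alpha, gamma
    )
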