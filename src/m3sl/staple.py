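"""STAPLE consensus fusion of imperfect rater masks.

Simultaneous Truth and Performance Level Estimation treats the unknown true
segmentation T and each rater's (sensitivity p_j, specificity q_j) as the
unknowns of an EM problem.  Given binary votes D_ij for rater j at voxel i
and a scalar foreground prior pi:

  E-step:  W_i = a_i / (a_i + b_i), with
           a_i = pi     * prod_j [ p_j      if D_ij else (1 - p_j) ]
           b_i = (1-pi) * prod_j [ (1-q_j)  if D_ij else q_j       ]
  M-step:  p_j = sum_{i: D_ij} W_i / sum_i W_i
           q_j = sum_{i: !D_ij} (1 - W_i) / sum_i (1 - W_i)

iterated until the largest absolute parameter change drops below ``tol``.
Voxels where every rater votes background share one closed-form posterior,
so the per-voxel work is restricted to a bounding box around the union of
the input foregrounds — the result is identical to the dense computation.

The fused probability map thresholded at 0.5 is the "silver standard" mask
of the training curriculum: a consensus estimate of the true lesions that is
more reliable than any single automated ("bronze") mask.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentError, DegenerateInputError
from .types import BinaryMask

DEFAULT_EPS = 1e-5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_INIT = 0.99


@dataclass
class RaterPerformance:
    """Estimated sensitivity/specificity of one rater."""

    rater_id: str
    p: float  # sensitivity
    q: float  # specificity


@dataclass
class StapleResult:
    consensus_prob: np.ndarray  # 3D, values in [0, 1]
    performances: List[RaterPerformance]
    iterations: int
    converged: bool
    prior: float
    loglik_trace: List[float]  # observed-data log-likelihood per iteration


def _as_bool_stack(masks: Sequence[BinaryMask]) -> np.ndarray:
    if len(masks) < 2:
        raise ValueError(f"STAPLE needs >= 2 masks, got {len(masks)}")
    shape = masks[0].data.shape
    for k, m in enumerate(masks[1:], start=1):
        if m.data.shape != shape:
            raise AlignmentError(
                f"mask {k} shape {m.data.shape} != mask 0 shape {shape}"
            )
    return np.stack([m.data.astype(bool) for m in masks], axis=0)


def staple(
    masks: Sequence[BinaryMask],
    prior: Optional[float] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    eps: float = DEFAULT_EPS,
    init_pq: float = DEFAULT_INIT,
    margin: int = 1,
) -> StapleResult:
    """Run STAPLE EM on >= 2 aligned binary masks.

    Parameters
    ----------
    masks
        Aligned rater masks (the bronze tier of the curriculum).
    prior
        Foreground prior pi; defaults to the majority-vote foreground
        fraction of the inputs.  (The mean per-rater foreground fraction is
        biased upward by rater false positives — each rater's FPs are its
        own, so their union inflates the apparent prevalence and deflates
        the sensitivity estimates; coincident majority votes on background
        are rare, so the majority-vote fraction tracks true prevalence.)
        Held fixed across iterations.
    tol, max_iter
        EM stops when max |delta p_j|, |delta q_j| < tol, or after max_iter.
    eps
        p, q are clamped to [eps, 1 - eps] to avoid degenerate products.
    init_pq
        Initial value for every p_j and q_j (symmetric, rater-trusting).
    margin
        Extra voxels kept around the union-foreground bounding box.  Voxels
        outside the box (where all raters voted background) are handled in
        closed form; the result equals the dense computation exactly.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    votes = _as_bool_stack(masks)  # (R, X, Y, Z)
    R = votes.shape[0]
    grid_shape = votes.shape[1:]
    n_total = int(np.prod(grid_shape))

    union = votes.any(axis=0)
    if not union.any():
        raise DegenerateInputError(
            "all rater masks are empty: no foreground evidence to fuse"
        )

    if prior is None:
        prior = float((votes.sum(axis=0) > votes.shape[0] / 2.0).mean())
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie in (0, 1), got {prior}")

    # bounding box of the union + margin
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, grid_shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    D = votes[(slice(None),) + box].reshape(R, -1).astype(np.float64)  # (R, V)
    n_box = D.shape[1]
    n_bg = n_total - n_box  # voxels outside the box: all raters vote False

    p = np.full(R, init_pq, dtype=np.float64)
    q = np.full(R, init_pq, dtype=np.float64)

    loglik_trace: List[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step (log domain for numerical stability)
        log_a = np.log(prior) + (
            D * np.log(p)[:, None] + (1 - D) * np.log1p(-p)[:, None]
        ).sum(axis=0)
        log_b = np.log1p(-prior) + (
            D * np.log1p(-q)[:, None] + (1 - D) * np.log(q)[:, None]
        ).sum(axis=0)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        W = a / (a + b)
        ll = float((m + np.log(a + b)).sum())

        # closed-form posterior of an all-background voxel
        log_a0 = np.log(prior) + np.log1p(-p).sum()
        log_b0 = np.log1p(-prior) + np.log(q).sum()
        m0 = max(log_a0, log_b0)
        a0, b0 = np.exp(log_a0 - m0), np.exp(log_b0 - m0)
        W0 = a0 / (a0 + b0)
        ll += n_bg * (m0 + np.log(a0 + b0))
        loglik_trace.append(ll)

        # M-step (background voxels contribute n_bg * W0 to the totals)
        sum_W = W.sum() + n_bg * W0
        sum_notW = (1.0 - W).sum() + n_bg * (1.0 - W0)
        p_new = (D * W[None, :]).sum(axis=1) / sum_W
        q_new = (((1 - D) * (1.0 - W)[None, :]).sum(axis=1) + n_bg * (1.0 - W0)) / sum_notW
        p_new = np.clip(p_new, eps, 1.0 - eps)
        q_new = np.clip(q_new, eps, 1.0 - eps)

        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    # final E-step with the converged parameters
    log_a = np.log(prior) + (
        D * np.log(p)[:, None] + (1 - D) * np.log1p(-p)[:, None]
    ).sum(axis=0)
    log_b = np.log1p(-prior) + (
        D * np.log1p(-q)[:, None] + (1 - D) * np.log(q)[:, None]
    ).sum(axis=0)
    m = np.maximum(log_a, log_b)
    W = 1.0 / (1.0 + np.exp(log_b - log_a))
    log_a0 = np.log(prior) + np.log1p(-p).sum()
    log_b0 = np.log1p(-prior) + np.log(q).sum()
    W0 = 1.0 / (1.0 + np.exp(log_b0 - log_a0))

    consensus = np.full(grid_shape, W0, dtype=np.float64)
    consensus[box] = W.reshape(tuple(int(b - a) for a, b in zip(lo, hi)))

    performances = [
        RaterPerformance(
            rater_id=masks[j].subject_id or f"rater{j}", p=float(p[j]), q=float(q[j])
        )
        for j in range(R)
    ]
    return StapleResult(
        consensus_prob=consensus,
        performances=performances,
        iterations=iterations,
        converged=converged,
        prior=prior,
        loglik_trace=loglik_trace,
    )


def binarize_consensus(
    r: StapleResult, threshold: float = 0.5, subject_id: str = ""
) -> BinaryMask:
    """Materialize the silver mask: voxel True iff posterior >= threshold.

    The tie rule is inclusive (probability exactly 0.5 maps to True),
    matching the network's 0.5 output dichotomization convention.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return BinaryMask(
        data=r.consensus_prob >= threshold, role="silver", subject_id=subject_id
    )


def majority_vote(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Baseline fusion: voxel True iff strictly more than half vote True."""
    votes = _as_bool_stack(masks)
    fused = votes.sum(axis=0) > votes.shape[0] / 2.0
    return BinaryMask(data=fused, role="silver", subject_id=masks[0].subject_id)
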