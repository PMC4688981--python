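"""Label fusion: STAPLE (EM) consensus and a majority-vote baseline.

STAPLE (Simultaneous Truth and Performance Level Estimation) treats the J
input segmentations ("raters") as noisy observations of a hidden true binary
segmentation T.  Rater j is characterised by a sensitivity p_j = P(D_ij=1 |
T_i=1) and a specificity q_j = P(D_ij=0 | T_i=0).  With a foreground prior
f1, EM alternates:

E-step, per voxel i::

    a_i = f1      * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
    b_i = (1-f1)  * prod_j q_j^(1-D_ij) (1-q_j)^D_ij
    W_i = a_i / (a_i + b_i)        # posterior P(T_i = 1 | D, p, q)

M-step, per rater j::

    p_j = sum_i W_i D_ij / sum_i W_i
    q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)

The consensus mask thresholds the posterior at 0.5.  For speed the E/M sums
are restricted to the bounding box of the union of rater foregrounds; every
voxel outside has D_ij = 0 for all j, so those voxels share one posterior
value and enter the M-step sums analytically.  The result is identical to
running EM over the full grid (tested against a full-grid reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume import GridMismatchError, LabelVolume

logger = logging.getLogger(__name__)

#: Probability clamp guarding against 0-division / log(0) degeneracies.
PROB_EPS = 1e-10


@dataclass
class FusionConfig:
    """Settings for :func:`staple`.

    ``prior``: foreground prior f1; ``"auto"`` uses the mean foreground
    fraction across raters.  ``init_performance``: warm-start value for all
    p_j and q_j.  Convergence: max absolute change in any p_j or q_j < tol.
    """

    prior: float | str = "auto"
    tol: float = 1e-6
    max_iter: int = 100
    threshold: float = 0.5
    init_performance: float = 0.9


@dataclass
class FusionResult:
    """STAPLE output: consensus mask, posterior map and rater performance."""

    consensus: LabelVolume
    posterior: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    n_iterations: int
    converged: bool


def _stack_raters(raters: list[LabelVolume]) -> np.ndarray:
    if not raters:
        raise ValueError("at least one rater segmentation is required")
    ref = raters[0]
    for r in raters[1:]:
        ref.require_same_grid(r)
    return np.stack([r.voxels.astype(bool) for r in raters])


def majority_vote(raters: list[LabelVolume]) -> LabelVolume:
    """Voxelwise strict-majority consensus; ties (even rater counts) vote 0."""
    votes = _stack_raters(raters)
    consensus = votes.sum(axis=0) > len(raters) / 2.0
    return raters[0].with_voxels(consensus.astype(np.uint8))


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, PROB_EPS, 1.0 - PROB_EPS)


def staple(
    raters: list[LabelVolume],
    prior: float | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 100,
    threshold: float = 0.5,
    init_performance: float = 0.9,
) -> FusionResult:
    """Fuse binary segmentations with the STAPLE EM algorithm.

    Deterministic: no randomness is involved.  The returned posterior is the
    E-step evaluated at the final (p, q) estimates, so it is always
    consistent with the reported performance parameters.

    Parameters
    ----------
    raters
        Binary segmentations on identical grids (>= 1).
    prior
        Foreground prior f1 in (0, 1), or ``"auto"`` for the mean foreground
        fraction across raters.
    tol, max_iter
        EM stops when the max absolute change in any p_j/q_j drops below
        ``tol``, or after ``max_iter`` iterations.
    threshold
        Posterior cut for the consensus mask (``posterior >= threshold``).
    init_performance
        Initial value of every p_j and q_j (clamped to (0, 1)).
    """
    D_full = _stack_raters(raters)  # (J, X, Y, Z) boolean
    grid = raters[0]
    n_raters = D_full.shape[0]
    n_total = int(np.prod(grid.shape))

    if prior == "auto":
        f1 = float(D_full.mean())
    else:
        f1 = float(prior)
        if not 0.0 < f1 < 1.0:
            raise ValueError(f"prior must be in (0, 1), got {prior}")
    f1 = float(np.clip(f1, PROB_EPS, 1.0 - PROB_EPS))

    # Bounding box of the union of foregrounds; outside it every rater votes
    # 0, so one shared posterior value covers all n_out background voxels.
    union = D_full.any(axis=0)
    if union.any():
        idx = np.nonzero(union)
        lo = [int(ax.min()) for ax in idx]
        hi = [int(ax.max()) + 1 for ax in idx]
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
    else:
        box = (slice(0, 0), slice(0, 0), slice(0, 0))
    D = D_full[(slice(None),) + box].reshape(n_raters, -1)  # (J, N_box)
    n_box = D.shape[1]
    n_out = n_total - n_box

    p = np.full(n_raters, float(np.clip(init_performance, PROB_EPS, 1 - PROB_EPS)))
    q = p.copy()

    def e_step(p, q):
        pc, qc = _clamp(p), _clamp(q)
        log_a = np.log(f1) + (
            D * np.log(pc)[:, None] + (~D) * np.log(1 - pc)[:, None]
        ).sum(axis=0)
        log_b = np.log1p(-f1) + (
            (~D) * np.log(qc)[:, None] + D * np.log(1 - qc)[:, None]
        ).sum(axis=0)
        with np.errstate(over="ignore"):
            W = 1.0 / (1.0 + np.exp(log_b - log_a))
        log_a_out = np.log(f1) + np.log(1 - pc).sum()
        log_b_out = np.log1p(-f1) + np.log(qc).sum()
        W_out = 1.0 / (1.0 + np.exp(log_b_out - log_a_out))
        return W, float(W_out)

    n_iterations = 0
    converged = False
    for _ in range(max_iter):
        W, W_out = e_step(p, q)
        sum_w = W.sum() + n_out * W_out
        sum_1w = (1.0 - W).sum() + n_out * (1.0 - W_out)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_new = np.where(sum_w > 0, (W[None, :] * D).sum(axis=1) / sum_w, p)
            q_new = np.where(
                sum_1w > 0,
                (((1.0 - W)[None, :] * (~D)).sum(axis=1) + n_out * (1.0 - W_out))
                / sum_1w,
                q,
            )
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        n_iterations += 1
        if delta < tol:
            converged = True
            break

    W, W_out = e_step(p, q)
    posterior = np.full(grid.shape, W_out, dtype=float)
    posterior[box] = W.reshape(D_full[(slice(None),) + box].shape[1:])
    consensus = grid.with_voxels((posterior >= threshold).astype(np.uint8))
    logger.debug(
        "STAPLE: %d raters, %d iterations, converged=%s", n_raters, n_iterations,
        converged,
    )
    return FusionResult(
        consensus=consensus,
        posterior=posterior,
        sensitivities=p,
        specificities=q,
        n_iterations=n_iterations,
        converged=converged,
    )


def staple_from_config(raters: list[LabelVolume], config: FusionConfig) -> FusionResult:
    """:func:`staple` with settings taken from a :class:`FusionConfig`."""
    return staple(
        raters,
        prior=config.prior,
        tol=config.tol,
        max_iter=config.max_iter,
        threshold=config.threshold,
        init_performance=config.init_performance,
    )
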