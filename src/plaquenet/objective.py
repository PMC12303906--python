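"""Joint training objective: L = alpha * L_seg + beta * L_size.

L_seg is mean per-pixel softmax cross-entropy of the class scores against
the label mask; L_size is the mean squared error of the two regressed
diameters.  Both terms use *mean* reduction so that their balance is
independent of batch and image size.  Besides fixed (alpha, beta), an
automatic balancing mode based on learnable homoscedastic task
uncertainties is provided: each task's weight is derived from a trained
log-variance, so the optimizer itself settles the segmentation/size
trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "segmentation_loss",
    "size_loss",
    "joint_loss",
    "UncertaintyBalancer",
]


@dataclass
class LossWeights:
    """alpha weights the segmentation term, beta the size term."""

    alpha: float = 1.0
    beta: float = 1.0
    mode: str = "fixed"  # "fixed" or "auto"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha + self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")
        if self.mode not in ("fixed", "auto"):
            raise ValueError("mode must be 'fixed' or 'auto'")


@dataclass
class LossBreakdown:
    total: float
    seg_term: float
    size_term: float
    alpha_used: float
    beta_used: float


def _softmax(scores: np.ndarray) -> np.ndarray:
    m = scores.max(axis=1, keepdims=True)
    e = np.exp(scores - m)
    return e / e.sum(axis=1, keepdims=True)


def segmentation_loss(scores: np.ndarray, mask: np.ndarray,
                      return_grad: bool = False):
    """Mean per-pixel cross-entropy of softmax(scores) against integer labels.

    ``scores``: (N, K, H, W) unnormalized; ``mask``: (N, H, W) ints in [0, K).
    """
    n, k, h, w = scores.shape
    mask = np.asarray(mask)
    if mask.shape != (n, h, w):
        raise ValueError("mask shape does not match scores")
    if mask.min() < 0 or mask.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    p = _softmax(scores.astype(np.float64))
    idx = mask.astype(np.intp)
    p_true = np.take_along_axis(p, idx[:, None], axis=1)[:, 0]
    npix = n * h * w
    loss = float(-np.log(np.maximum(p_true, 1e-300)).sum() / npix)
    if not return_grad:
        return loss
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx[:, None], 1.0, axis=1)
    grad = (p - onehot) / npix
    return loss, grad


def size_loss(pred: np.ndarray, truth: np.ndarray, return_grad: bool = False):
    """Mean squared error over all diameter entries (N x 2 of them)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    diff = pred - truth
    loss = float(np.mean(diff ** 2))
    if not return_grad:
        return loss
    return loss, 2.0 * diff / diff.size


def joint_loss(scores, mask, pred, truth, weights: LossWeights,
               return_grads: bool = False):
    """Weighted joint loss; optionally also the gradients w.r.t. both heads."""
    if weights.alpha + weights.beta == 0:
        raise ValueError("alpha and beta cannot both be zero")
    seg, dseg = segmentation_loss(scores, mask, return_grad=True)
    size, dsize = size_loss(pred, truth, return_grad=True)
    bd = LossBreakdown(
        total=weights.alpha * seg + weights.beta * size,
        seg_term=seg,
        size_term=size,
        alpha_used=weights.alpha,
        beta_used=weights.beta,
    )
    if not return_grads:
        return bd
    return bd, weights.alpha * dseg, weights.beta * dsize


class UncertaintyBalancer:
    """Learnable task balancing via homoscedastic uncertainties.

    Maintains two scalars s_seg, s_size (log-variances) and forms

        total = exp(-s_seg) * L_seg + s_seg + 0.5 * exp(-s_size) * L_size + 0.5 * s_size

    so the effective weights are alpha = exp(-s_seg), beta = 0.5 * exp(-s_size).
    A task whose raw loss stays large drives its log-variance up, shrinking
    its weight; the regularizing +s terms stop the weights collapsing to 0.
    """

    def __init__(self, lr: float = 1e-2):
        self.s_seg = 0.0
        self.s_size = 0.0
        self.lr = lr
        # Adam state for the two scalars
        self._m = np.zeros(2)
        self._v = np.zeros(2)
        self._t = 0

    @property
    def weights(self) -> LossWeights:
        return LossWeights(alpha=float(np.exp(-self.s_seg)),
                           beta=float(0.5 * np.exp(-self.s_size)),
                           mode="auto")

    def total(self, seg: float, size: float) -> float:
        return (np.exp(-self.s_seg) * seg + self.s_seg
                + 0.5 * np.exp(-self.s_size) * size + 0.5 * self.s_size)

    def step(self, seg: float, size: float) -> None:
        """One Adam update of (s_seg, s_size) on the current raw losses."""
        g = np.array([
            -np.exp(-self.s_seg) * seg + 1.0,
            -0.5 * np.exp(-self.s_size) * size + 0.5,
        ])
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._m = b1 * self._m + (1 - b1) * g
        self._v = b2 * self._v + (1 - b2) * g * g
        mh = self._m / (1 - b1 ** self._t)
        vh = self._v / (1 - b2 ** self._t)
        upd = self.lr * mh / (np.sqrt(vh) + eps)
        self.s_seg -= float(upd[0])
        self.s_size -= float(upd[1])
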