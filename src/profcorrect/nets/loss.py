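"""Evenly weighted soft-Dice + cross-entropy loss with deep supervision.

The loss operates on raw per-voxel class scores (logits). Cross-entropy uses
a numerically stable log-softmax; the soft Dice term is computed per
foreground class over the whole batch as 1 - 2*sum(p*t) / (sum(p) + sum(t)
+ eps) and averaged over foreground classes. Analytic gradients w.r.t. the
logits are returned alongside the value, so training does not need autodiff
through the loss itself.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

EPS = 1e-5


class NumericError(FloatingPointError):
    """Scores became non-finite."""


def _softmax(logits: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    z = e.sum(axis=1, keepdims=True)
    return e / z, shifted - np.log(z)  # probs, log-probs


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    oh = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        oh[:, c] = target == c
    return oh


def _downsample_labels(target: np.ndarray, shape) -> np.ndarray:
    """Strided nearest-neighbour label downsampling to a coarser scale."""
    steps = tuple(t // s for t, s in zip(target.shape[1:], shape))
    return target[:, :: steps[0], :: steps[1], :: steps[2]][:, : shape[0], : shape[1], : shape[2]]


def dice_ce_with_grad(logits: np.ndarray, target: np.ndarray
                      ) -> Tuple[float, np.ndarray]:
    """Single-scale 0.5*Dice + 0.5*CE and its gradient w.r.t. the logits.

    ``logits``: (N, C, D, H, W); ``target``: (N, D, H, W) integer labels.
    """
    if not np.all(np.isfinite(logits)):
        raise NumericError("non-finite scores")
    n, c = logits.shape[:2]
    probs, logp = _softmax(logits)
    onehot = _one_hot(target, c)
    nvox = target.size

    ce = -float((onehot * logp).sum()) / nvox

    # batch soft Dice over foreground classes
    axes = (0, 2, 3, 4)
    inter = (probs * onehot).sum(axis=axes)          # per class
    denom = probs.sum(axis=axes) + onehot.sum(axis=axes)
    fg = slice(1, c)
    dice_per_class = 1.0 - 2.0 * inter[fg] / (denom[fg] + EPS)
    n_fg = c - 1
    dice = float(dice_per_class.mean()) if n_fg else 0.0

    # gradients
    d_ce = (probs - onehot) / nvox
    d_dice_dp = np.zeros_like(probs)
    if n_fg:
        for cls in range(1, c):
            u = denom[cls] + EPS
            d_dice_dp[:, cls] = (-2.0 * onehot[:, cls] / u
                                 + 2.0 * inter[cls] / u ** 2) / n_fg
    # softmax backward: dL/dz = p * (dL/dp - sum_c dL/dp_c * p_c)
    inner = (d_dice_dp * probs).sum(axis=1, keepdims=True)
    d_dice = probs * (d_dice_dp - inner)

    loss = 0.5 * dice + 0.5 * ce
    grad = (0.5 * d_dice + 0.5 * d_ce).astype(np.float32)
    return loss, grad


def loss_components(logits: np.ndarray, target: np.ndarray) -> Tuple[float, float]:
    """(soft-Dice term, cross-entropy term) of the single-scale loss."""
    _, logp = _softmax(logits)
    c = logits.shape[1]
    onehot = _one_hot(target, c)
    ce = -float((onehot * logp).sum()) / target.size
    loss, _ = dice_ce_with_grad(logits, target)
    return 2.0 * (loss - 0.5 * ce), ce


def combined_loss(scores: Sequence[np.ndarray], target: np.ndarray,
                  ds_weights: Optional[Sequence[float]] = None) -> float:
    """Deep-supervised loss value over score maps (finest scale first)."""
    return multiscale_loss_with_grads(scores, target, ds_weights)[0]


def multiscale_loss_with_grads(scores: Sequence[np.ndarray], target: np.ndarray,
                               ds_weights: Optional[Sequence[float]] = None
                               ) -> Tuple[float, List[np.ndarray]]:
    """Weighted multi-scale loss and per-scale logit gradients.

    Weights are normalized to sum 1; targets are downsampled (nearest) to
    each supervised resolution.
    """
    if ds_weights is None:
        w = np.ones(len(scores))
    else:
        w = np.asarray(list(ds_weights), dtype=float)
    if len(w) != len(scores):
        raise ValueError("need one weight per score map")
    if w.sum() <= 0:
        raise ValueError("deep-supervision weights must sum to a positive value")
    w = w / w.sum()

    total = 0.0
    grads: List[np.ndarray] = []
    for weight, sc in zip(w, scores):
        if weight == 0.0:
            grads.append(np.zeros_like(sc))
            continue
        tgt = target if sc.shape[2:] == target.shape[1:] else \
            _downsample_labels(target, sc.shape[2:])
        loss, grad = dice_ce_with_grad(sc, tgt)
        total += weight * loss
        grads.append(weight * grad)
    return float(total), grads
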