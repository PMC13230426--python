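"""Patch-based training and sliding-window prediction.

Training follows the usual 3D segmentation recipe: random patches (a third
of them centred on a foreground voxel so small tumors are not starved),
seeded augmentation, SGD with nesterov momentum and weight decay, and
polynomial learning-rate decay over the full step budget. Prediction tiles
the volume with half-overlapping patches blended under a Gaussian importance
map. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .augment import augment
from .config import NetConfigError, TrainConfig
from .loss import NumericError, multiscale_loss_with_grads
from .unet import UNet3D, deep_supervision_weights


class DataError(ValueError):
    """Dataset unusable for training (empty, malformed)."""


class DivergenceError(FloatingPointError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class Sample:
    """One training case: image channels (C, D, H, W) + integer target (D, H, W)."""

    channels: np.ndarray
    target: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.target = np.asarray(self.target)
        if self.channels.ndim != 4 or self.target.ndim != 3 \
                or self.channels.shape[1:] != self.target.shape:
            raise DataError(f"sample {self.case_id!r}: channels {self.channels.shape} "
                            f"vs target {self.target.shape}")


def _pad_to(arr: np.ndarray, shape, mode="edge") -> np.ndarray:
    pads = [(0, max(0, s - a)) for a, s in zip(arr.shape[-3:], shape)]
    if arr.ndim == 4:
        pads = [(0, 0)] + pads
    if not any(p[1] for p in pads):
        return arr
    if mode == "zero":
        return np.pad(arr, pads)
    return np.pad(arr, pads, mode="edge")


def _extract_patch(sample: Sample, patch_size, rng: np.random.Generator,
                   force_fg: bool) -> Tuple[np.ndarray, np.ndarray]:
    ch = _pad_to(sample.channels, patch_size)
    tg = _pad_to(sample.target[None], patch_size, mode="zero")[0]
    shape = np.asarray(tg.shape)
    psz = np.asarray(patch_size)
    max_lo = shape - psz
    if force_fg:
        fg = np.argwhere(tg > 0)
        if fg.size:
            center = fg[rng.integers(len(fg))]
            lo = np.clip(center - psz // 2, 0, max_lo)
        else:
            lo = np.array([rng.integers(m + 1) for m in max_lo])
    else:
        lo = np.array([rng.integers(m + 1) for m in max_lo])
    sl = tuple(slice(int(l), int(l + p)) for l, p in zip(lo, psz))
    return ch[(slice(None),) + sl].copy(), tg[sl].copy()


class SGD:
    """SGD with (optionally nesterov) momentum and decoupled-style weight decay."""

    def __init__(self, params, momentum: float, nesterov: bool, weight_decay: float):
        self.params = params
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            update = g + self.momentum * v if self.nesterov else v
            p.data -= (lr * update).astype(np.float32)


def _foreground_dice(pred: np.ndarray, target: np.ndarray) -> float:
    """Hard Dice of all foreground classes pooled, for validation tracking."""
    p = pred > 0
    t = target > 0
    denom = p.sum() + t.sum()
    return 1.0 if denom == 0 else 2.0 * float((p & t).sum()) / float(denom)


def train(model: UNet3D, dataset: Sequence[Sample], config: TrainConfig,
          val_dataset: Optional[Sequence[Sample]] = None,
          intensity_channels: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Train in place; returns a per-epoch history (loss, lr, val_dice).

    A third of the patches (``config.foreground_oversample``) are centred on
    foreground voxels. Validation, when a validation set is given, is a hard
    foreground Dice on the central patch of each validation case, evaluated
    every ``config.validate_every`` iterations and averaged per epoch.
    """
    dataset = list(dataset)
    if not dataset:
        raise DataError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.params, config.momentum, config.nesterov, config.weight_decay)
    patch = model.config.patch_size
    ds_w = deep_supervision_weights(len(model.forward(
        np.zeros((1, model.config.in_channels) + tuple(patch), np.float32))))

    history = []
    step = 0
    for epoch in range(config.epochs):
        epoch_losses = []
        val_scores: List[float] = []
        for it in range(config.iters_per_epoch):
            batch_ch, batch_tg = [], []
            for b in range(config.batch_size):
                sample = dataset[rng.integers(len(dataset))]
                force_fg = rng.uniform() < config.foreground_oversample
                ch, tg = _extract_patch(sample, patch, rng, force_fg)
                ch, tg = augment(ch, tg, config.augmentation,
                                 seed=int(rng.integers(2 ** 31)),
                                 intensity_channels=intensity_channels)
                batch_ch.append(ch)
                batch_tg.append(tg)
            x = np.stack(batch_ch)
            y = np.stack(batch_tg).astype(np.int64)

            model.zero_grad()
            outputs = model.forward(x)
            try:
                loss, grads = multiscale_loss_with_grads(
                    [o.data for o in outputs], y, ds_w)
            except NumericError as exc:
                raise DivergenceError(epoch) from exc
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            for out, g in zip(outputs, grads):
                if np.any(g):
                    out.backward(g)
            lr = config.lr_at(step)
            opt.step(lr)
            step += 1
            epoch_losses.append(loss)

            if val_dataset and (step % config.validate_every == 0):
                val_scores.append(_validate(model, val_dataset, patch))

        history.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                        "lr": config.lr_at(step - 1),
                        "val_dice": float(np.mean(val_scores)) if val_scores else np.nan})
    return pd.DataFrame(history)


def _validate(model: UNet3D, val_dataset: Sequence[Sample], patch) -> float:
    scores = []
    for sample in val_dataset:
        ch = _pad_to(sample.channels, patch)
        tg = _pad_to(sample.target[None], patch, mode="zero")[0]
        lo = [(s - p) // 2 for s, p in zip(tg.shape, patch)]
        sl = tuple(slice(l, l + p) for l, p in zip(lo, patch))
        pred = model.forward(ch[(slice(None),) + sl][None])[0].data[0].argmax(axis=0)
        scores.append(_foreground_dice(pred, tg[sl]))
    return float(np.mean(scores))


def _gaussian_importance(patch_size, sigma_scale: float = 0.125) -> np.ndarray:
    grids = [np.arange(p) - (p - 1) / 2.0 for p in patch_size]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    sig = [max(p * sigma_scale, 1.0) for p in patch_size]
    w = np.exp(-0.5 * ((zz / sig[0]) ** 2 + (yy / sig[1]) ** 2 + (xx / sig[2]) ** 2))
    return (w / w.max()).astype(np.float32)


def predict(model: UNet3D, channels: np.ndarray, overlap: float = 0.5,
            mirror_tta: bool = False) -> np.ndarray:
    """Sliding-window argmax prediction at the input's full resolution.

    ``channels``: (C, D, H, W) normalized exactly as in training. Volumes
    smaller than the patch are padded (edge mode) and the result unpadded.
    With ``mirror_tta`` the class probabilities are averaged over all eight
    axis-flip combinations, which makes the prediction exactly equivariant
    to mirroring (at 8x the compute).
    """
    probs = predict_probs(model, channels, overlap=overlap, mirror_tta=mirror_tta)
    return probs.argmax(axis=0).astype(np.int16)


def predict_probs(model: UNet3D, channels: np.ndarray, overlap: float = 0.5,
                  mirror_tta: bool = False) -> np.ndarray:
    """Per-class probability maps, (n_classes, D, H, W)."""
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 4 or channels.shape[0] != model.config.in_channels:
        raise NetConfigError(f"expected ({model.config.in_channels}, D, H, W) input, "
                             f"got {channels.shape}")
    if mirror_tta:
        import itertools
        acc = None
        for flips in itertools.product((False, True), repeat=3):
            axes = tuple(i + 1 for i, f in enumerate(flips) if f)
            x = np.flip(channels, axis=axes) if axes else channels
            p = predict_probs(model, np.ascontiguousarray(x), overlap=overlap)
            p = np.flip(p, axis=axes) if axes else p
            acc = p if acc is None else acc + p
        return acc / 8.0
    orig_shape = channels.shape[1:]
    patch = tuple(model.config.patch_size)
    padded = _pad_to(channels, patch)
    shape = padded.shape[1:]

    starts = []
    for n, p in zip(shape, patch):
        if n == p:
            starts.append([0])
        else:
            stride = max(1, int(p * (1 - overlap)))
            pos = list(range(0, n - p, stride)) + [n - p]
            starts.append(sorted(set(pos)))

    n_classes = model.config.out_channels
    acc = np.zeros((n_classes,) + shape, dtype=np.float32)
    wsum = np.zeros(shape, dtype=np.float32)
    importance = _gaussian_importance(patch)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                      slice(x0, x0 + patch[2]))
                logits = model.forward(padded[(slice(None),) + sl][None])[0].data[0]
                shifted = logits - logits.max(axis=0, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=0, keepdims=True)
                acc[(slice(None),) + sl] += probs * importance
                wsum[sl] += importance
    acc /= np.maximum(wsum, 1e-8)
    return acc[:, : orig_shape[0], : orig_shape[1], : orig_shape[2]]
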