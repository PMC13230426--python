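"""Seeded data augmentation for (channels, target) training samples.

Spatial transforms (rotation, scaling, mirroring) are applied identically to
every channel and to the target, with nearest-neighbour interpolation for
integer-valued grids so labels stay labels. Intensity transforms (noise,
blur, brightness, contrast) touch only the designated image channels — in
the professor's dual-channel input the teacher-mask channel is passed
through untouched.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import AugmentParams


def _rotation_scale_matrix(rng: np.random.Generator, params: AugmentParams) -> np.ndarray:
    angles = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg, size=3))
    cz, sz = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cx, sx = np.cos(angles[2]), np.sin(angles[2])
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])   # rotation about z keeps z-axis
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    scale = rng.uniform(*params.scale_range)
    return (rz @ ry @ rx) / scale


def _apply_affine(arr: np.ndarray, matrix: np.ndarray, order: int) -> np.ndarray:
    center = (np.asarray(arr.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="nearest", output=arr.dtype if order == 0 else None)


def augment(channels: np.ndarray, target: Optional[np.ndarray], params: AugmentParams,
            seed: int, intensity_channels: Optional[Sequence[int]] = None
            ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Augment one sample. ``channels``: (C, D, H, W); ``target``: (D, H, W) or None.

    ``intensity_channels`` restricts noise/blur/brightness/contrast to those
    channel indices (default: all channels). Deterministic per ``seed``.
    """
    rng = np.random.default_rng(seed)
    channels = np.asarray(channels, dtype=np.float32).copy()
    target = None if target is None else np.asarray(target).copy()
    if intensity_channels is None:
        intensity_channels = list(range(channels.shape[0]))

    if params.p_spatial > 0 and rng.uniform() < params.p_spatial:
        m = _rotation_scale_matrix(rng, params)
        for c in range(channels.shape[0]):
            order = 0 if c not in intensity_channels else 1  # label-like channels: nearest
            channels[c] = _apply_affine(channels[c], m, order=order)
        if target is not None:
            target = _apply_affine(target, m, order=0)

    for axis in params.mirror_axes:
        if rng.uniform() < params.p_mirror:
            channels = np.flip(channels, axis=axis + 1)
            if target is not None:
                target = np.flip(target, axis=axis)

    if params.p_noise > 0 and rng.uniform() < params.p_noise:
        for c in intensity_channels:
            channels[c] = channels[c] + rng.normal(
                0.0, params.gaussian_noise_sd, size=channels[c].shape).astype(np.float32)
    if params.p_blur > 0 and rng.uniform() < params.p_blur:
        sigma = rng.uniform(*params.blur_sigma_range)
        for c in intensity_channels:
            channels[c] = ndimage.gaussian_filter(channels[c], sigma)
    if params.p_brightness > 0 and rng.uniform() < params.p_brightness:
        factor = rng.uniform(*params.brightness_range)
        for c in intensity_channels:
            channels[c] = channels[c] * factor
    if params.p_contrast > 0 and rng.uniform() < params.p_contrast:
        factor = rng.uniform(*params.contrast_range)
        for c in intensity_channels:
            mean = channels[c].mean()
            channels[c] = (channels[c] - mean) * factor + mean

    channels = np.ascontiguousarray(channels)
    if target is not None:
        target = np.ascontiguousarray(target)
    return channels, target
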