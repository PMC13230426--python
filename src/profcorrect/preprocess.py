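"""Cropping to the mask-union bounding box, CT normalization, and restoring
cropped correction maps to the original grid.

The professor operates on a crop around the tumor: the axis-aligned bounding
box of (ground truth OR teacher mask), optionally padded by a margin. After
the professor predicts a correction map on the crop, :func:`restore` places
it back into the full grid, filling the outside with the background code 0 —
which decodes to keep-the-teacher-value, so the restore step never edits
voxels the professor never saw.

Boxes are half-open ``[lo, hi)``, 0-based, in (z, y, x) voxel indices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence, Tuple

import numpy as np

from .grids import BinaryMask, Volume, check_aligned

Int3 = Tuple[int, int, int]


class EmptyUnionError(ValueError):
    """Both masks are empty; no bounding box exists."""


class StatsError(ValueError):
    """Normalization statistics cannot be computed (empty or constant foreground)."""


@dataclass
class CropSpec:
    """Half-open crop box [lo, hi) with the original shape it was cut from."""

    lo: Int3
    hi: Int3
    original_shape: Int3
    margin: int = 0

    def __post_init__(self):
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        self.original_shape = tuple(int(v) for v in self.original_shape)
        for lo, hi, n in zip(self.lo, self.hi, self.original_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"invalid crop box {self.lo}..{self.hi} in shape {self.original_shape}")

    @property
    def shape(self) -> Int3:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    @property
    def slices(self):
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CropSpec":
        return cls(**json.loads(s))


@dataclass
class NormStats:
    """Clip-then-standardize CT normalization parameters.

    ``clip_lo``/``clip_hi`` are intensity clip bounds, ``mean``/``sd`` the
    post-clip standardization constants, all computed on pooled foreground
    voxels of a training set (recorded in ``source``).
    """

    clip_lo: float
    clip_hi: float
    mean: float
    sd: float
    source: str = ""

    def __post_init__(self):
        if not self.clip_lo < self.clip_hi:
            raise ValueError(f"clip_lo must be < clip_hi, got {self.clip_lo}, {self.clip_hi}")
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        return cls(**json.loads(s))


def mask_bbox(mask: BinaryMask, margin: int = 0) -> CropSpec:
    """Tight bounding box of a single mask, padded by ``margin``, clamped to the grid.

    Used at pure inference time, when no ground truth exists and the union
    box cannot be formed: the teacher mask's own box stands in.
    """
    nz = np.nonzero(mask.data)
    if nz[0].size == 0:
        raise EmptyUnionError("mask is empty; no bounding box")
    lo = [max(0, int(idx.min()) - margin) for idx in nz]
    hi = [min(n, int(idx.max()) + 1 + margin) for idx, n in zip(nz, mask.data.shape)]
    return CropSpec(tuple(lo), tuple(hi), tuple(mask.data.shape), margin)


def union_bbox(mask_a: BinaryMask, mask_b: BinaryMask, margin: int = 0) -> CropSpec:
    """Bounding box of (mask_a OR mask_b), padded by ``margin``, clamped to the grid."""
    check_aligned(mask_a, mask_b)
    union = BinaryMask(np.maximum(mask_a.data, mask_b.data), mask_a.spacing, mask_a.origin)
    try:
        return mask_bbox(union, margin)
    except EmptyUnionError:
        raise EmptyUnionError("both masks empty; union bounding box undefined") from None


def crop(grid, spec: CropSpec):
    """Cut the [lo, hi) box out of a Volume/BinaryMask/CorrectionMap."""
    if tuple(grid.data.shape) != spec.original_shape:
        raise ValueError(f"grid shape {grid.data.shape} does not match crop spec "
                         f"original_shape {spec.original_shape}")
    return grid.with_data(grid.data[spec.slices].copy())


def restore(cropped, spec: CropSpec):
    """Place a cropped grid back at [lo, hi) in a zero-filled full-size grid."""
    if tuple(cropped.data.shape) != spec.shape:
        raise ValueError(f"cropped shape {cropped.data.shape} does not match crop "
                         f"spec box shape {spec.shape}")
    full = np.zeros(spec.original_shape, dtype=cropped.data.dtype)
    full[spec.slices] = cropped.data
    return cropped.with_data(full)


def normalize_ct(volume: Volume, stats: NormStats) -> Volume:
    """Clip to [clip_lo, clip_hi] then standardize: (clip(x) - mean) / sd."""
    data = np.clip(volume.data.astype(np.float32), stats.clip_lo, stats.clip_hi)
    return volume.with_data((data - stats.mean) / stats.sd)


def compute_norm_stats(volumes: Sequence[Volume], foreground_masks: Sequence[BinaryMask],
                       source: str = "", percentiles: Tuple[float, float] = (0.5, 99.5)
                       ) -> NormStats:
    """Pool foreground intensities across a training set and derive NormStats.

    Clip bounds are the 0.5/99.5 percentiles of pooled foreground voxels,
    mean/sd are computed on the clipped pool. Background voxels never enter.
    """
    if len(volumes) != len(foreground_masks) or not volumes:
        raise ValueError("need equal, non-zero numbers of volumes and masks")
    pools = []
    for vol, msk in zip(volumes, foreground_masks):
        check_aligned(vol, msk)
        fg = vol.data[msk.data > 0]
        if fg.size:
            pools.append(np.asarray(fg, dtype=np.float64))
    if not pools:
        raise StatsError("no foreground voxels in any volume")
    pool = np.concatenate(pools)
    clip_lo, clip_hi = np.percentile(pool, percentiles)
    if not clip_lo < clip_hi:
        raise StatsError("degenerate foreground: clip bounds coincide")
    clipped = np.clip(pool, clip_lo, clip_hi)
    sd = float(clipped.std())
    if sd <= 0:
        raise StatsError("zero foreground intensity variance")
    return NormStats(float(clip_lo), float(clip_hi), float(clipped.mean()), sd, source)
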