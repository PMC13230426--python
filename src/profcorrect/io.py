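"""NIfTI reading/writing, geometric validation and resampling.

On disk NIfTI stores arrays in (x, y, z) fastest-first order with an affine;
in memory everything is (z, y, x). The conversion happens only here, at the
boundary. Only axis-aligned (diagonal) affines are supported: oblique or
rotated acquisitions are rejected rather than silently mishandled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import BinaryMask, Volume, alignment_violations

GridLike = Union[Volume, BinaryMask]


class FormatError(ValueError):
    """File exists but is not a usable 3D axis-aligned NIfTI."""


def _affine_from_geometry(spacing_zyx, origin_zyx) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    oz, oy, ox = origin_zyx
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _geometry_from_affine(affine: np.ndarray):
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise FormatError("oblique/rotated affine not supported; reorient to axis-aligned first")
    diag = np.diag(rot)
    if np.any(diag == 0):
        raise FormatError("degenerate affine with zero spacing")
    spacing_xyz = np.abs(diag)
    origin_xyz = affine[:3, 3]
    return tuple(spacing_xyz[::-1]), tuple(float(v) for v in origin_xyz[::-1])


def _load(path) -> tuple:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt header / not a NIfTI
        raise FormatError(f"cannot read {path!r} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    spacing, origin = _geometry_from_affine(img.affine)
    return np.transpose(data, (2, 1, 0)), spacing, origin


def read_volume(path) -> Volume:
    """Read a 3D NIfTI scalar image, normalising axis order to (z, y, x)."""
    data, spacing, origin = _load(path)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path!r} contains non-finite voxels")
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def read_mask(path, binarize_threshold: float = 0.5) -> BinaryMask:
    """Read a NIfTI label/probability image and binarize at ``binarize_threshold``."""
    data, spacing, origin = _load(path)
    return BinaryMask((np.asarray(data, dtype=np.float64) > binarize_threshold).astype(np.uint8),
                      spacing, origin)


def write_volume(vol: Volume, path) -> None:
    data = np.transpose(np.asarray(vol.data, dtype=np.float32), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine_from_geometry(vol.spacing, vol.origin)), path)


def write_mask(mask: BinaryMask, path) -> None:
    data = np.transpose(np.asarray(mask.data, dtype=np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine_from_geometry(mask.spacing, mask.origin)), path)


def write_labels(data_zyx: np.ndarray, spacing, origin, path) -> None:
    """Write an integer label/code grid (e.g. a correction map) as NIfTI."""
    arr = np.transpose(np.asarray(data_zyx, dtype=np.int16), (2, 1, 0))
    nib.save(nib.Nifti1Image(arr, _affine_from_geometry(spacing, origin)), path)


def read_labels(path) -> tuple:
    """Read an integer grid; returns (data zyx, spacing, origin)."""
    data, spacing, origin = _load(path)
    return np.asarray(np.rint(data), dtype=np.int16), spacing, origin


@dataclass
class AlignmentVerdict:
    ok: bool
    violations: List[str]

    def __bool__(self) -> bool:
        return self.ok


def validate_alignment(volume: GridLike, mask: GridLike, tolerance: float = 1e-6) -> AlignmentVerdict:
    """Check that two grids share shape, spacing and origin within ``tolerance``."""
    problems = alignment_violations(volume, mask, tolerance)
    return AlignmentVerdict(not problems, problems)


def resample(grid: GridLike, target_spacing: Sequence[float], mode: str = "linear") -> GridLike:
    """Resample a grid to ``target_spacing`` (mm, z/y/x).

    ``mode`` must be ``"linear"`` for intensity volumes and ``"nearest"`` for
    masks and integer code grids; nearest never invents label values. Output
    shape is chosen so physical extent is preserved to within one voxel.
    """
    target = np.asarray([float(s) for s in target_spacing], dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError(f"target_spacing must be 3 positive values, got {target_spacing}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    is_int = np.issubdtype(np.asarray(grid.data).dtype, np.integer)
    if mode == "linear" and is_int:
        raise ValueError("linear interpolation on integer label grids would invent values; "
                         "use mode='nearest'")

    src = np.asarray(grid.spacing, dtype=float)
    if np.allclose(src, target):
        return grid.with_data(grid.data.copy())
    new_shape = np.maximum(1, np.rint(np.asarray(grid.data.shape) * src / target)).astype(int)
    zoom = new_shape / np.asarray(grid.data.shape)
    order = 1 if mode == "linear" else 0
    out = ndimage.zoom(np.asarray(grid.data, dtype=float if order else grid.data.dtype),
                       zoom, order=order, mode="nearest", grid_mode=True)
    out = out[: new_shape[0], : new_shape[1], : new_shape[2]]
    if is_int:
        out = out.astype(grid.data.dtype)
    else:
        out = out.astype(np.float32)
    result = grid.with_data(out)
    result.spacing = tuple(target)
    return result
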