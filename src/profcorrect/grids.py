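"""In-memory containers for 3D grids.

All grids use (z, y, x) axis order, matching the z-first convention of
clinical CT spacing reports (e.g. slice thickness × in-plane resolution).
Spacing is in millimetres per voxel along each axis; origin is the physical
position (mm) of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

Triple = Tuple[float, float, float]


class AlignmentError(ValueError):
    """Two grids that must share geometry do not."""


def _as_triple(v) -> Triple:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(eq=False)
class Volume:
    """A 3D scalar image (CT-like intensities, Hounsfield-style units)."""

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with positive shape, got {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass(eq=False)
class BinaryMask:
    """A 3D {0,1} segmentation mask aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"mask must be 3D with positive shape, got {self.data.shape}")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8, copy=False)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=data)


def check_aligned(a, b, tolerance: float = 1e-6) -> None:
    """Raise :class:`AlignmentError` unless two grids share shape and geometry."""
    problems = alignment_violations(a, b, tolerance)
    if problems:
        raise AlignmentError("; ".join(problems))


def alignment_violations(a, b, tolerance: float = 1e-6) -> list:
    """List of human-readable geometry mismatches between two grids (empty = aligned)."""
    problems = []
    if tuple(a.data.shape) != tuple(b.data.shape):
        problems.append(f"shape mismatch: {tuple(a.data.shape)} vs {tuple(b.data.shape)}")
    for name in ("spacing", "origin"):
        va, vb = np.asarray(getattr(a, name)), np.asarray(getattr(b, name))
        if np.any(np.abs(va - vb) > tolerance):
            problems.append(f"{name} mismatch: {tuple(va)} vs {tuple(vb)}")
    return problems
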