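"""Correction-matrix encoding and application.

The professor model's training target is a voxel-wise *correction map*
``y_corr`` built from the teacher mask ``y_teach`` and ground truth
``y_true``. Each voxel falls into one of four categories:

====  ==========  =========  ==============================
code  y_teach     y_true     meaning
====  ==========  =========  ==============================
TN    0           0          correctly labelled background
FN    0           1          tumor the teacher missed
FP    1           0          spurious teacher tumor
TP    1           1          correctly labelled tumor
====  ==========  =========  ==============================

A :class:`CorrectionScheme` assigns an integer code to FN, FP and TP; TN
voxels carry ``y_teach`` (i.e. 0). Decoding turns codes back into actions on
the teacher mask: FN and TP codes set the voxel to 1, the FP code sets it to
0, and the background code 0 keeps the teacher value. Schemes may reuse a
code across categories with the same action, and may deliberately collapse a
category onto the background code (losing it): Precision Priority encodes
only TP, so decoding leaves teacher errors untouched, and the Underestimation
Focuser drops FP, so false positives survive correction. These lossy
round-trips are intended behaviour, not defects — each scheme expresses a
hypothesis about which teacher errors are learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np

from .grids import BinaryMask, check_aligned

# voxel categories
TN, FN, FP, TP = 0, 1, 2, 3

# decode actions
KEEP = "keep"    # output = y_teach
SET_ONE = "set1"  # output = 1
SET_ZERO = "set0"  # output = 0


class SchemeConflictError(ValueError):
    """A nonzero code is claimed by categories with contradictory actions."""


class DecodeError(ValueError):
    """A correction map contains a code its scheme does not define."""


@dataclass(frozen=True)
class CorrectionScheme:
    """Named assignment of integer codes to the FN/FP/TP voxel categories."""

    name: str
    fn_code: int
    fp_code: int
    tp_code: int

    def __post_init__(self):
        for v in (self.fn_code, self.fp_code, self.tp_code):
            if v < 0 or int(v) != v:
                raise ValueError(f"codes must be non-negative integers, got {v}")
        decode_table(self)  # raises SchemeConflictError on contradiction

    @property
    def codes(self) -> Tuple[int, ...]:
        """Sorted set of codes a map under this scheme may contain (incl. background 0)."""
        return tuple(sorted({0, self.fn_code, self.fp_code, self.tp_code}))

    @property
    def n_classes(self) -> int:
        """Number of distinct classes a professor predicting this scheme outputs."""
        return len(self.codes)


@dataclass(eq=False)
class CorrectionMap:
    """3D integer grid of scheme codes; the professor's target/prediction y_corr."""

    data: np.ndarray
    scheme: CorrectionScheme
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"correction map must be 3D, got shape {self.data.shape}")
        self.data = self.data.astype(np.int16, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(s) for s in self.origin)

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "CorrectionMap":
        return replace(self, data=data)


def categorize(y_teach: BinaryMask, y_true: BinaryMask) -> np.ndarray:
    """Per-voxel TN/FN/FP/TP categories from an aligned (teacher, truth) pair."""
    check_aligned(y_teach, y_true)
    t = y_teach.data.astype(np.int16)
    g = y_true.data.astype(np.int16)
    # (teach, true): (0,0)->TN (0,1)->FN (1,0)->FP (1,1)->TP
    return (g * (1 - t)) * FN + (t * (1 - g)) * FP + (t * g) * TP


def encode(y_teach: BinaryMask, y_true: BinaryMask, scheme: CorrectionScheme) -> CorrectionMap:
    """Build y_corr: FN/FP/TP voxels take their scheme code, TN voxels take y_teach (=0)."""
    cat = categorize(y_teach, y_true)
    lut = np.zeros(4, dtype=np.int16)
    lut[FN], lut[FP], lut[TP] = scheme.fn_code, scheme.fp_code, scheme.tp_code
    return CorrectionMap(lut[cat], scheme, y_teach.spacing, y_teach.origin)


def decode_table(scheme: CorrectionScheme) -> Dict[int, str]:
    """Map each code of a scheme to its action on the teacher mask.

    Construction: FN and TP codes act as SET_ONE, the FP code as SET_ZERO;
    code 0 is indistinguishable from background and always resolves to KEEP.
    Categories sharing a code must agree on the action, otherwise the scheme
    is self-contradictory.
    """
    claims = {}  # code -> action
    for code, action in ((scheme.fn_code, SET_ONE), (scheme.tp_code, SET_ONE),
                         (scheme.fp_code, SET_ZERO)):
        if code == 0:
            continue  # collides with background: falls back to keep-y_teach
        if claims.get(code, action) != action:
            raise SchemeConflictError(
                f"scheme {scheme.name!r}: code {code} demands both set-1 and set-0")
        claims[code] = action
    table = {0: KEEP}
    table.update(claims)
    return table


def apply_correction(y_teach: BinaryMask, corr: CorrectionMap) -> BinaryMask:
    """Apply a correction map to the teacher mask, producing y_prof.

    Voxels whose code decodes to SET_ONE become tumor, SET_ZERO become
    background, and the background code keeps the teacher's value.
    """
    if tuple(y_teach.data.shape) != tuple(corr.data.shape):
        raise ValueError(
            f"shape mismatch: teacher {y_teach.data.shape} vs map {corr.data.shape}")
    table = decode_table(corr.scheme)
    present = np.unique(corr.data)
    unknown = [int(c) for c in present if int(c) not in table]
    if unknown:
        raise DecodeError(f"map contains codes {unknown} undefined for scheme "
                          f"{corr.scheme.name!r} (valid: {sorted(table)})")
    out = y_teach.data.astype(np.uint8).copy()
    for code, action in table.items():
        if action == SET_ONE:
            out[corr.data == code] = 1
        elif action == SET_ZERO:
            out[corr.data == code] = 0
    return BinaryMask(out, y_teach.spacing, y_teach.origin)


# The four published schemes.
PRECISION_PRIORITY = CorrectionScheme("precision_priority", fn_code=0, fp_code=0, tp_code=1)
PATTERN_DISCERNER = CorrectionScheme("pattern_discerner", fn_code=1, fp_code=2, tp_code=3)
UNDERESTIMATION_FOCUSER = CorrectionScheme("underestimation_focuser", fn_code=1, fp_code=0, tp_code=2)
INCLUSIVE_CORRECTION = CorrectionScheme("inclusive_correction", fn_code=2, fp_code=1, tp_code=2)

SCHEMES: Dict[str, CorrectionScheme] = {
    s.name: s
    for s in (PRECISION_PRIORITY, PATTERN_DISCERNER, UNDERESTIMATION_FOCUSER,
              INCLUSIVE_CORRECTION)
}
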