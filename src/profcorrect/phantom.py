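"""Seeded synthetic CT-like phantoms with tumor/organ structures and a
configurable teacher-error simulator.

The generator emulates the inputs of a pancreatic-tumor segmentation study:
a soft-tissue background, one irregular (lobulated) tumor with an intensity
offset, a few ellipsoidal "organ" context structures with their own offsets,
and Gaussian acquisition noise. The paired error model corrupts the ground
truth the way an imperfect teacher network would — systematic boundary
under-/over-segmentation (erosion/dilation in mm), smooth boundary noise,
dropped tumor lobes (false-negative chunks) and spurious components (false
positives). Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryMask, Volume
from .io import write_mask, write_volume

BACKGROUND_HU = 60.0  # soft-tissue baseline intensity


class PhantomConfigError(ValueError):
    """Configuration cannot produce a valid phantom (e.g. tumor does not fit)."""


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of one phantom cohort.

    Defaults describe the desk-scale study volume: 48³ voxels at 1.5 mm
    isotropic spacing (a 72 mm cube), a lobulated tumor of 10–16 mm radius
    (hypodense, −40 HU against soft tissue), three organ-context ellipsoids
    and 10 HU Gaussian noise.
    """

    shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    tumor_radius_range: Tuple[float, float] = (10.0, 16.0)  # mm
    tumor_irregularity: float = 0.3    # relative amplitude of radial lobulation
    tumor_contrast: float = -40.0      # HU offset of tumor vs background
    n_context_organs: int = 3
    noise_sd: float = 10.0             # HU
    center_jitter_mm: float = 6.0      # tumor-centre jitter around volume centre

    def __post_init__(self):
        rmin, rmax = self.tumor_radius_range
        if not (0 < rmin <= rmax):
            raise PhantomConfigError(f"bad tumor radius range {self.tumor_radius_range}")
        if self.tumor_irregularity < 0 or self.noise_sd < 0 or self.n_context_organs < 0:
            raise PhantomConfigError("irregularity, noise_sd, n_context_organs must be >= 0")
        half_extent = min(n * s for n, s in zip(self.shape, self.spacing)) / 2.0
        if rmax * (1.0 + self.tumor_irregularity) + self.center_jitter_mm + 2.0 > half_extent:
            raise PhantomConfigError(
                f"max tumor radius {rmax} mm (+irregularity/jitter) does not fit in a "
                f"{[n * s for n, s in zip(self.shape, self.spacing)]} mm volume")


@dataclass
class ErrorModel:
    """Teacher-error simulator parameters (all sizes in mm).

    The default regime is erosion-dominant under-segmentation with mild
    boundary noise, occasional dropped lobes and rare spurious blobs; it is
    calibrated so the simulated teacher scores a mean DSC near 0.6 on the
    default phantom cohort.
    """

    erode_mm: float = 3.0
    dilate_mm: float = 0.0
    boundary_noise_sd: float = 1.0   # mm, smooth signed-distance perturbation
    fp_blob_rate: float = 0.3        # expected number of spurious components
    fn_dropout_prob: float = 0.25    # probability of deleting one tumor lobe
    seed: int = 0

    def __post_init__(self):
        if min(self.erode_mm, self.dilate_mm, self.boundary_noise_sd, self.fp_blob_rate) < 0:
            raise ValueError("rates and sizes must be >= 0")
        if not 0.0 <= self.fn_dropout_prob <= 1.0:
            raise ValueError("fn_dropout_prob must lie in [0, 1]")


def _smooth_field(shape, rng, sigma_vox=4.0) -> np.ndarray:
    """Zero-mean, unit-variance smooth random field (blurred white noise)."""
    w = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = w.std()
    return w / sd if sd > 0 else w


def _voxel_coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    zz, yy, xx = _voxel_coords_mm(shape, spacing)
    q = (((zz - center_mm[0]) / radii_mm[0]) ** 2
         + ((yy - center_mm[1]) / radii_mm[1]) ** 2
         + ((xx - center_mm[2]) / radii_mm[2]) ** 2)
    return q <= 1.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_phantom(config: PhantomConfig, seed: int):
    """One phantom: returns ``(Volume, BinaryMask gt, organ-label grid)``.

    The tumor is a sphere whose radius is modulated by a smooth random field
    (lobulated boundary); organs are ellipsoids with distinct intensity
    offsets, never overlapping the tumor. Identical seeds give bit-identical
    outputs.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = tuple(config.shape), tuple(config.spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    radius = rng.uniform(*config.tumor_radius_range)
    center = extent / 2.0 + rng.uniform(-1, 1, size=3) * config.center_jitter_mm

    zz, yy, xx = _voxel_coords_mm(shape, spacing)
    dist = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    if config.tumor_irregularity > 0:
        bump = _smooth_field(shape, rng)
        local_radius = radius * (1.0 + config.tumor_irregularity * bump)
    else:
        local_radius = np.full(shape, radius)
    tumor = dist <= local_radius
    tumor = _largest_component(tumor)
    if not tumor.any():  # degenerate irregularity draw: fall back to the raw sphere
        tumor = dist <= radius

    organ_labels = np.zeros(shape, dtype=np.int16)
    intensity = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    for organ_idx in range(1, config.n_context_organs + 1):
        radii = rng.uniform(6.0, 14.0, size=3)
        pos = rng.uniform(0.15, 0.85, size=3) * extent
        organ = _ellipsoid_mask(shape, spacing, pos, radii) & ~tumor & (organ_labels == 0)
        organ_labels[organ] = organ_idx
        offset = rng.uniform(-60.0, 60.0)
        intensity[organ] += offset

    intensity[tumor] = BACKGROUND_HU + config.tumor_contrast
    if config.noise_sd > 0:
        intensity += rng.normal(0.0, config.noise_sd, size=shape)

    vol = Volume(intensity.astype(np.float32), spacing)
    gt = BinaryMask(tumor.astype(np.uint8), spacing)
    return vol, gt, organ_labels


def _mm_structuring_element(radius_mm: float, spacing) -> Optional[np.ndarray]:
    """Ellipsoidal structuring element with per-axis radius round(mm/spacing) voxels."""
    r_vox = np.array([int(round(radius_mm / s)) for s in spacing])
    if np.all(r_vox == 0):
        return None
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    q = sum((g / max(r, 1)) ** 2 for g, r in zip(grids, r_vox))
    return q <= 1.0


def corrupt_segmentation(gt: BinaryMask, error_model: ErrorModel) -> BinaryMask:
    """Simulate a teacher pseudo-segmentation by corrupting the ground truth.

    Applied in order: lobe dropout, erosion, dilation, smooth boundary
    perturbation, spurious-component insertion. Deterministic for a fixed
    ``error_model.seed``.
    """
    rng = np.random.default_rng(error_model.seed)
    spacing = gt.spacing
    out = gt.data.astype(bool).copy()

    # 1. lobe dropout: carve a ball around a random surface voxel
    if out.any() and rng.uniform() < error_model.fn_dropout_prob:
        interior = ndimage.binary_erosion(out, border_value=0)
        surface = np.argwhere(out & ~interior)
        if surface.size:
            pick = surface[rng.integers(len(surface))]
            eq_radius_mm = ((3.0 * out.sum() * np.prod(spacing)) / (4.0 * np.pi)) ** (1 / 3)
            zz, yy, xx = _voxel_coords_mm(out.shape, spacing)
            center = pick * np.asarray(spacing)
            ball = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
                    ) <= (0.7 * eq_radius_mm) ** 2
            carved = out & ~ball
            if carved.any():
                out = carved

    # 2/3. systematic under-/over-segmentation
    se = _mm_structuring_element(error_model.erode_mm, spacing)
    if se is not None and out.any():
        out = ndimage.binary_erosion(out, structure=se, border_value=0)
    se = _mm_structuring_element(error_model.dilate_mm, spacing)
    if se is not None and out.any():
        out = ndimage.binary_dilation(out, structure=se)

    # 4. smooth boundary noise on the signed distance field (mm)
    if error_model.boundary_noise_sd > 0 and out.any() and not out.all():
        inside = ndimage.distance_transform_edt(out, sampling=spacing)
        outside = ndimage.distance_transform_edt(~out, sampling=spacing)
        sdf = outside - inside  # negative inside
        bump = _smooth_field(out.shape, rng)
        out = (sdf + error_model.boundary_noise_sd * bump) <= 0

    # 5. spurious components away from the tumor
    n_blobs = rng.poisson(error_model.fp_blob_rate)
    if n_blobs:
        keepout = ndimage.binary_dilation(gt.data.astype(bool), iterations=2)
        extent = np.array([n * s for n, s in zip(out.shape, spacing)])
        for _ in range(n_blobs):
            pos = rng.uniform(0.1, 0.9, size=3) * extent
            radii = rng.uniform(2.0, 5.0, size=3)
            blob = _ellipsoid_mask(out.shape, spacing, pos, radii) & ~keepout
            out |= blob

    return BinaryMask(out.astype(np.uint8), spacing, gt.origin)


@dataclass
class CohortRow:
    case_id: str
    patient_id: str
    volume_path: str
    gt_path: str
    teacher_path: str


MANIFEST_COLUMNS = ("case_id", "patient_id", "volume_path", "gt_path", "teacher_path")


def generate_cohort(n: int, config: PhantomConfig, error_model: ErrorModel, seed: int,
                    out_dir, multi_scan_fraction: float = 0.0,
                    tumor_free_fraction: float = 0.0,
                    intensity_shift_fraction: float = 0.0,
                    prefix: str = "case") -> pd.DataFrame:
    """Write ``n`` phantom (volume, gt, teacher) triplets plus a CSV manifest.

    Per-case seeds derive from the master ``seed`` through a SeedSequence
    spawn, so cohorts are reproducible and cases independent. A
    ``multi_scan_fraction`` of cases are second scans of already-seen
    patients; ``tumor_free_fraction`` cases have empty ground truth (control
    analogue); ``intensity_shift_fraction`` cases get a global intensity
    offset (different contrast-phase analogue).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(n)]
    assign_rng = np.random.default_rng(master.spawn(1)[0])

    n_dup = int(round(multi_scan_fraction * n))
    n_primary = n - n_dup
    patient_ids = [f"{prefix}-pt{idx:03d}" for idx in range(n_primary)]
    if n_dup:
        extras = assign_rng.choice(n_primary, size=n_dup, replace=n_dup > n_primary)
        patient_ids += [f"{prefix}-pt{idx:03d}" for idx in extras]

    n_free = int(round(tumor_free_fraction * n))
    n_shift = int(round(intensity_shift_fraction * n))
    free_idx = set(assign_rng.choice(n, size=n_free, replace=False)) if n_free else set()
    shift_idx = set(assign_rng.choice(n, size=n_shift, replace=False)) if n_shift else set()

    rows = []
    for i in range(n):
        vol, gt, _ = generate_phantom(config, case_seeds[i])
        if i in free_idx:
            gt = gt.with_data(np.zeros_like(gt.data))
        if i in shift_idx:
            vol = vol.with_data(vol.data + 80.0)
        teach = corrupt_segmentation(
            gt, ErrorModel(**{**error_model.__dict__, "seed": case_seeds[i] ^ 0x5EED}))
        case_id = f"{prefix}-{i:03d}"
        paths = {k: os.path.join(out_dir, f"{case_id}_{k}.nii.gz")
                 for k in ("volume", "gt", "teacher")}
        write_volume(vol, paths["volume"])
        write_mask(gt, paths["gt"])
        write_mask(teach, paths["teacher"])
        rows.append(CohortRow(case_id, patient_ids[i], paths["volume"],
                              paths["gt"], paths["teacher"]))
    manifest = pd.DataFrame([r.__dict__ for r in rows], columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
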