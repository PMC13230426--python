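"""Three-phase experiment orchestration.

Phase 1 trains the teacher on manually labelled cases with patient-grouped
cross-validation and produces *out-of-fold* pseudo-labels: each case is
segmented by the fold model that never saw it. Phase 2 trains one professor
per fold and per correction scheme on (CT, teacher mask) → correction-map
targets, scores every scheme by the Dice of its corrected out-of-fold
segmentations, and selects the best. Phase 3 applies the selected professor
(fold-ensemble majority vote) to unlabelled cases' teacher masks and trains
the student on manual plus corrected labels.

At desk scale the teacher can be *simulated*: the phantom module's error
model already provides corrupted teacher masks, so the pipeline's learning
claims can be tested without spending the teacher's training budget.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .corrmap import (SCHEMES, CorrectionMap, CorrectionScheme, apply_correction, encode)
from .grids import BinaryMask, Volume
from .metrics import MetricsReport, dsc, evaluate_cohort
from .nets import (NetConfig, Sample, TrainConfig, UNet3D, build_unet, predict,
                   preset_configs, train)
from .phantom import ErrorModel, PhantomConfig, generate_cohort
from .preprocess import (CropSpec, EmptyUnionError, NormStats, compute_norm_stats,
                         crop, mask_bbox, normalize_ct, restore, union_bbox)

logger = logging.getLogger("profcorrect")


class ConfigurationError(ValueError):
    pass


class PhaseError(RuntimeError):
    """A pipeline phase failed; partial outputs are preserved on disk."""

    def __init__(self, phase: str, cause: Exception):
        super().__init__(f"phase {phase!r} failed: {cause}")
        self.phase = phase


# ---------------------------------------------------------------------------
# fold assignment


@dataclass
class FoldAssignment:
    """Patient-grouped, balanced, seeded k-fold assignment."""

    mapping: Dict[str, int]
    k: int
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.mapping[patient_id]

    def cases_in_fold(self, manifest: pd.DataFrame, fold: int) -> pd.DataFrame:
        mask = manifest["patient_id"].map(self.mapping) == fold
        return manifest[mask]

    def cases_not_in_fold(self, manifest: pd.DataFrame, fold: int) -> pd.DataFrame:
        mask = manifest["patient_id"].map(self.mapping) != fold
        return manifest[mask]


def assign_folds(patient_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Assign each patient to one of ``k`` folds, balanced to within one patient.

    All scans of a patient share its fold, preventing patient-level leakage
    between training and validation partitions.
    """
    unique = sorted(set(patient_ids))
    if len(unique) < k:
        raise ConfigurationError(f"need at least {k} patients for {k} folds, "
                                 f"got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    mapping = {pid: i % k for i, pid in enumerate(order)}
    return FoldAssignment(mapping, k, seed)


# ---------------------------------------------------------------------------
# phase bookkeeping


@dataclass
class PhasePlan:
    """Declarative description of one training phase (for logs/provenance)."""

    phase: str                      # teacher | professor | student
    label_source: str               # manual | teacher_oof | professor_corrected+manual
    preset: str
    out_dir: str

    def __post_init__(self):
        valid = {"teacher": {"manual"},
                 "professor": {"teacher_oof"},
                 "student": {"professor_corrected+manual", "manual"}}
        if self.phase not in valid:
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if self.label_source not in valid[self.phase]:
            raise ConfigurationError(
                f"phase {self.phase!r} cannot train from {self.label_source!r}")


# ---------------------------------------------------------------------------
# case loading / preparation


@dataclass(eq=False)
class Case:
    case_id: str
    patient_id: str
    volume: Volume
    gt: Optional[BinaryMask] = None
    teacher: Optional[BinaryMask] = None


def load_cases(manifest: pd.DataFrame) -> List[Case]:
    cases = []
    for _, row in manifest.iterrows():
        vol = pio.read_volume(row["volume_path"])
        gt = pio.read_mask(row["gt_path"]) if _has(row, "gt_path") else None
        teach = pio.read_mask(row["teacher_path"]) if _has(row, "teacher_path") else None
        cases.append(Case(str(row["case_id"]), str(row["patient_id"]), vol, gt, teach))
    return cases


def _has(row, col) -> bool:
    return col in row and isinstance(row[col], str) and len(row[col]) > 0


def _resample_case(case: Case, spacing) -> Case:
    if np.allclose(case.volume.spacing, spacing):
        return case
    return Case(case.case_id, case.patient_id,
                pio.resample(case.volume, spacing, "linear"),
                pio.resample(case.gt, spacing, "nearest") if case.gt else None,
                pio.resample(case.teacher, spacing, "nearest") if case.teacher else None)


def _segmentation_sample(case: Case, stats: NormStats, extra_mask: Optional[BinaryMask] = None
                         ) -> Sample:
    channels = [normalize_ct(case.volume, stats).data]
    if extra_mask is not None:
        channels.append(extra_mask.data.astype(np.float32))
    return Sample(np.stack(channels), case.gt.data.astype(np.int64), case.case_id)


# ---------------------------------------------------------------------------
# phase 1: teacher


@dataclass
class TeacherResult:
    models: List[UNet3D]
    stats: NormStats
    folds: FoldAssignment
    manifest: pd.DataFrame        # with teacher_path pointing at OOF pseudo-labels
    provenance: pd.DataFrame      # case_id, fold, predicted_by_fold


def phase1_teacher(manifest: pd.DataFrame, preset: NetConfig, train_config: TrainConfig,
                   folds: FoldAssignment, out_dir) -> TeacherResult:
    """Cross-validated teacher training + out-of-fold pseudo-label generation."""
    if manifest["gt_path"].isna().any():
        raise ConfigurationError("every teacher-phase case needs a manual ground truth")
    os.makedirs(out_dir, exist_ok=True)
    PhasePlan("teacher", "manual", preset.name, str(out_dir))
    cases = [_resample_case(c, preset.target_spacing) for c in load_cases(manifest)]
    native = {c.case_id: c for c in load_cases(manifest)}
    stats = compute_norm_stats([c.volume for c in cases if c.gt.data.any()],
                               [c.gt for c in cases if c.gt.data.any()],
                               source=f"teacher training set n={len(cases)}")

    by_fold = {c.case_id: folds.fold_of(c.patient_id) for c in cases}
    models, prov_rows = [], []
    manifest = manifest.copy()
    for f in range(folds.k):
        train_cases = [c for c in cases if by_fold[c.case_id] != f]
        samples = [_segmentation_sample(c, stats) for c in train_cases]
        model = build_unet(preset.with_channels(in_channels=1, out_channels=2),
                           seed=train_config.seed + f)
        t0 = time.time()
        train(model, samples, dataclasses.replace(train_config, seed=train_config.seed + f))
        logger.info("teacher fold %d trained on %d cases in %.1fs",
                    f, len(samples), time.time() - t0)
        model.save(os.path.join(out_dir, f"teacher_fold{f}.npz.pkl"))
        models.append(model)

    for c in cases:
        f = by_fold[c.case_id]
        pred = predict(models[f], np.stack([normalize_ct(c.volume, stats).data]))
        mask = BinaryMask((pred > 0).astype(np.uint8), c.volume.spacing, c.volume.origin)
        native_case = native[c.case_id]
        if not np.allclose(mask.spacing, native_case.volume.spacing):
            mask = pio.resample(mask, native_case.volume.spacing, "nearest")
            mask = _match_shape(mask, native_case.volume.shape)
        path = os.path.join(out_dir, f"{c.case_id}_teacher_oof.nii.gz")
        pio.write_mask(mask, path)
        manifest.loc[manifest["case_id"] == c.case_id, "teacher_path"] = path
        prov_rows.append({"case_id": c.case_id, "fold": f, "predicted_by_fold": f,
                          "in_training_of_predictor": False})
    provenance = pd.DataFrame(prov_rows)
    provenance.to_csv(os.path.join(out_dir, "teacher_oof_provenance.csv"), index=False)
    manifest.to_csv(os.path.join(out_dir, "manifest_with_oof.csv"), index=False)
    return TeacherResult(models, stats, folds, manifest, provenance)


def _match_shape(mask: BinaryMask, shape) -> BinaryMask:
    """Pad/crop a resampled mask to an exact voxel shape (rounding jitter)."""
    data = mask.data
    pads = [(0, max(0, s - d)) for d, s in zip(data.shape, shape)]
    if any(p[1] for p in pads):
        data = np.pad(data, pads)
    data = data[: shape[0], : shape[1], : shape[2]]
    return BinaryMask(data, mask.spacing, mask.origin)


def cascade_stage2_channels(case: Case, lowres_seg: BinaryMask, stats: NormStats
                            ) -> np.ndarray:
    """Input channels for the full-resolution stage of a two-stage cascade:
    the normalized CT plus the low-resolution segmentation upsampled
    (nearest) onto the full-resolution grid."""
    seg = lowres_seg
    if not np.allclose(seg.spacing, case.volume.spacing):
        seg = _match_shape(pio.resample(seg, case.volume.spacing, "nearest"),
                           case.volume.shape)
    return np.stack([normalize_ct(case.volume, stats).data,
                     seg.data.astype(np.float32)])


# ---------------------------------------------------------------------------
# phase 2: professor


@dataclass
class ProfessorBundle:
    """Everything needed to apply the selected professor to new cases."""

    scheme: CorrectionScheme
    models: List[UNet3D]
    stats: NormStats
    margin: int
    spacing: Tuple[float, float, float]


@dataclass
class ProfessorResult:
    selected: ProfessorBundle
    ranking: pd.DataFrame          # scheme, mean_dsc, sd_dsc, per-fold scores
    fold_models: Dict[str, List[UNet3D]]


def _code_lut(scheme: CorrectionScheme):
    """scheme codes <-> contiguous class indices for the softmax head."""
    codes = list(scheme.codes)
    to_class = {code: i for i, code in enumerate(codes)}
    return codes, to_class


def _professor_sample(case: Case, scheme: CorrectionScheme, stats: NormStats,
                      margin: int) -> Optional[Sample]:
    try:
        spec = union_bbox(case.gt, case.teacher, margin)
    except EmptyUnionError:
        return None
    vol_c = normalize_ct(crop(case.volume, spec), stats)
    teach_c = crop(case.teacher, spec)
    gt_c = crop(case.gt, spec)
    corr = encode(teach_c, gt_c, scheme)
    codes, to_class = _code_lut(scheme)
    target = np.zeros(corr.data.shape, dtype=np.int64)
    for code, cls in to_class.items():
        target[corr.data == code] = cls
    channels = np.stack([vol_c.data, teach_c.data.astype(np.float32)])
    return Sample(channels, target, case.case_id)


def correct_case(case: Case, bundle: ProfessorBundle) -> BinaryMask:
    """Professor-correct one case's teacher mask (fold-ensemble majority vote).

    The crop box is the union bounding box when ground truth is available;
    at pure inference it falls back to the teacher mask's own box. An empty
    teacher mask (nothing to correct, no crop region) passes through.
    """
    native_spacing = case.volume.spacing
    rcase = _resample_case(case, bundle.spacing)
    try:
        if rcase.gt is not None:
            spec = union_bbox(rcase.gt, rcase.teacher, bundle.margin)
        else:
            spec = mask_bbox(rcase.teacher, bundle.margin)
    except EmptyUnionError:
        return case.teacher
    vol_c = normalize_ct(crop(rcase.volume, spec), bundle.stats)
    teach_c = crop(rcase.teacher, spec)
    channels = np.stack([vol_c.data, teach_c.data.astype(np.float32)])
    codes, _ = _code_lut(bundle.scheme)
    lut = np.asarray(codes, dtype=np.int16)

    votes = np.zeros(teach_c.data.shape, dtype=np.int32)
    for model in bundle.models:
        classes = predict(model, channels)
        code_map = CorrectionMap(lut[classes], bundle.scheme,
                                 teach_c.spacing, teach_c.origin)
        corrected_crop = apply_correction(teach_c, code_map)
        votes += corrected_crop.data
    majority = (votes * 2 > len(bundle.models)).astype(np.uint8)
    corrected_full = restore(BinaryMask(majority, teach_c.spacing), spec)
    # outside the crop the teacher mask is untouched; inside, the vote decides
    data = rcase.teacher.data.copy()
    data[spec.slices] = corrected_full.data[spec.slices]
    out = BinaryMask(data, rcase.teacher.spacing, rcase.teacher.origin)
    if not np.allclose(out.spacing, native_spacing):
        out = pio.resample(out, native_spacing, "nearest")
        out = _match_shape(out, case.volume.shape)
    return out


def phase2_professor(manifest: pd.DataFrame, schemes: Sequence[CorrectionScheme],
                     preset: NetConfig, train_config: TrainConfig,
                     folds: FoldAssignment, out_dir,
                     margin: int = 4, oracle: bool = False) -> ProfessorResult:
    """Train/evaluate professors for every scheme; select the best by CV Dice.

    With ``oracle=True`` the network is replaced by the exact encode-then-
    apply round trip, which scores each scheme's information ceiling (the
    lossless schemes reach Dice 1.0 by construction) without any training.
    """
    os.makedirs(out_dir, exist_ok=True)
    PhasePlan("professor", "teacher_oof", preset.name, str(out_dir))
    if not schemes:
        raise ConfigurationError("need at least one correction scheme")
    cases = [_resample_case(c, preset.target_spacing) for c in load_cases(manifest)]
    for c in cases:
        if c.teacher is None or c.gt is None:
            raise ConfigurationError(f"case {c.case_id}: professor phase needs both "
                                     "ground truth and teacher pseudo-label")
    usable = [c for c in cases if c.gt.data.any() or c.teacher.data.any()]
    usable_ids = {c.case_id for c in usable}
    skipped = [c.case_id for c in cases if c.case_id not in usable_ids]
    if skipped:
        logger.info("phase2: skipping %d empty-union cases: %s", len(skipped), skipped)
    stats = compute_norm_stats([c.volume for c in usable if c.gt.data.any()],
                               [c.gt for c in usable if c.gt.data.any()],
                               source=f"professor training set n={len(usable)}")
    by_fold = {c.case_id: folds.fold_of(c.patient_id) for c in usable}

    rank_rows = []
    fold_models: Dict[str, List[UNet3D]] = {}
    for scheme in schemes:
        per_fold_scores: List[float] = []
        models: List[UNet3D] = []
        case_scores: List[float] = []
        for f in range(folds.k):
            train_cs = [c for c in usable if by_fold[c.case_id] != f]
            val_cs = [c for c in usable if by_fold[c.case_id] == f]
            if oracle:
                model = None
            else:
                samples = [s for s in (_professor_sample(c, scheme, stats, margin)
                                       for c in train_cs) if s is not None]
                cfg = preset.with_channels(in_channels=2, out_channels=scheme.n_classes)
                model = build_unet(cfg, seed=train_config.seed + 31 * f)
                train(model, samples,
                      dataclasses.replace(train_config, seed=train_config.seed + 31 * f),
                      intensity_channels=[0])
                models.append(model)
            fold_scores = []
            for c in val_cs:
                if oracle:
                    corrected = apply_correction(c.teacher, encode(c.teacher, c.gt, scheme))
                else:
                    bundle = ProfessorBundle(scheme, [model], stats, margin,
                                             tuple(preset.target_spacing))
                    corrected = correct_case(c, bundle)
                fold_scores.append(dsc(corrected, c.gt))
            if fold_scores:
                per_fold_scores.append(float(np.mean(fold_scores)))
                case_scores.extend(fold_scores)
        rank_rows.append({"scheme": scheme.name,
                          "mean_dsc": float(np.mean(case_scores)),
                          "sd_dsc": float(np.std(case_scores)),
                          "fold_dscs": per_fold_scores,
                          "n_cases": len(case_scores)})
        fold_models[scheme.name] = models

    ranking = pd.DataFrame(rank_rows).sort_values("mean_dsc", ascending=False,
                                                  kind="stable").reset_index(drop=True)
    ranking.to_csv(os.path.join(out_dir, "scheme_ranking.csv"), index=False)
    best_name = ranking.iloc[0]["scheme"]
    best_scheme = next(s for s in schemes if s.name == best_name)
    bundle = ProfessorBundle(best_scheme, fold_models[best_name], stats, margin,
                             tuple(preset.target_spacing))
    if not oracle:
        for i, m in enumerate(fold_models[best_name]):
            m.save(os.path.join(out_dir, f"professor_{best_name}_fold{i}.pkl"))
    with open(os.path.join(out_dir, "selected_scheme.json"), "w") as fh:
        json.dump({"name": best_scheme.name, "fn_code": best_scheme.fn_code,
                   "fp_code": best_scheme.fp_code, "tp_code": best_scheme.tp_code}, fh)
    logger.info("phase2 selected scheme %s (mean CV DSC %.3f)",
                best_name, ranking.iloc[0]["mean_dsc"])
    return ProfessorResult(bundle, ranking, fold_models)


# ---------------------------------------------------------------------------
# phase 3: student


@dataclass
class StudentResult:
    model: UNet3D
    stats: NormStats
    provenance: pd.DataFrame
    corrected_manifest: pd.DataFrame


def phase3_student(labeled_manifest: pd.DataFrame, unlabeled_manifest: Optional[pd.DataFrame],
                   professor: ProfessorBundle, preset: NetConfig,
                   train_config: TrainConfig, out_dir) -> StudentResult:
    """Correct unlabelled pseudo-labels, then train the student on everything."""
    os.makedirs(out_dir, exist_ok=True)
    PhasePlan("student", "professor_corrected+manual", preset.name, str(out_dir))
    labeled = [_resample_case(c, preset.target_spacing) for c in load_cases(labeled_manifest)]
    prov_rows = [{"case_id": c.case_id, "label_source": "manual"} for c in labeled]

    corrected_cases: List[Case] = []
    corrected_rows = []
    if unlabeled_manifest is not None and len(unlabeled_manifest):
        for case in load_cases(unlabeled_manifest):
            if case.teacher is None:
                raise ConfigurationError(f"unlabeled case {case.case_id} has no "
                                         "teacher pseudo-label to correct")
            case.gt = None  # unlabeled by definition; inference-style crop box
            corrected = correct_case(case, professor)
            path = os.path.join(out_dir, f"{case.case_id}_corrected.nii.gz")
            pio.write_mask(corrected, path)
            corrected_rows.append({"case_id": case.case_id, "corrected_path": path})
            prov_rows.append({"case_id": case.case_id, "label_source": "professor_corrected"})
            rcase = _resample_case(
                Case(case.case_id, case.patient_id, case.volume, corrected, None),
                preset.target_spacing)
            corrected_cases.append(rcase)

    all_cases = labeled + corrected_cases
    with_fg = [c for c in all_cases if c.gt.data.any()]
    stats = compute_norm_stats([c.volume for c in with_fg], [c.gt for c in with_fg],
                               source=f"student training set n={len(all_cases)}")
    samples = [_segmentation_sample(c, stats) for c in all_cases]
    model = build_unet(preset.with_channels(in_channels=1, out_channels=2),
                       seed=train_config.seed + 977)
    train(model, samples, train_config)
    model.save(os.path.join(out_dir, "student.pkl"))
    provenance = pd.DataFrame(prov_rows)
    provenance.to_csv(os.path.join(out_dir, "label_provenance.csv"), index=False)
    corrected_manifest = pd.DataFrame(corrected_rows)
    return StudentResult(model, stats, provenance, corrected_manifest)


# ---------------------------------------------------------------------------
# full pipeline


DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "out_dir": "experiment",
    "folds": 2,
    "phantom": {},
    "error_model": {},
    "cohort": {"n_labeled": 40, "n_test": 10, "n_unlabeled": 0,
               "multi_scan_fraction": 0.1, "tumor_free_fraction": 0.0,
               "intensity_shift_fraction": 0.0},
    "teacher": {"mode": "simulated", "preset": "tiny_test",
                "train": {"epochs": 2, "iters_per_epoch": 10}},
    "professor": {"preset": "tiny_test", "margin": 4, "oracle": False,
                  "schemes": ["underestimation_focuser"],
                  "train": {"epochs": 8, "iters_per_epoch": 25}},
    "student": {"enabled": False, "preset": "tiny_test",
                "train": {"epochs": 2, "iters_per_epoch": 10}},
}


def desk_scale_config(seed: int, out_dir: str,
                      schemes: Sequence[str] = ("underestimation_focuser",)) -> dict:
    """The desk-scale experiment: 40 training + 10 held-out phantoms (48³),
    the erosion-dominant default error model (simulated teacher, mean DSC
    ≈ 0.6), two patient-grouped folds and a short tiny-preset professor
    training run. A CPU-budget analogue of the clinical study design."""
    return {
        "seed": int(seed),
        "out_dir": out_dir,
        "folds": 2,
        "cohort": {"n_labeled": 40, "n_test": 10, "n_unlabeled": 0,
                   "multi_scan_fraction": 0.1},
        "teacher": {"mode": "simulated"},
        "professor": {"preset": "tiny_test", "margin": 4,
                      "schemes": list(schemes),
                      "train": {"epochs": 6, "iters_per_epoch": 25}},
        "student": {"enabled": False},
    }


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _train_config(d: dict, seed: int, folds: int, light_augment: bool = True) -> TrainConfig:
    from .nets import AugmentParams
    aug = AugmentParams(p_spatial=0.1, p_blur=0.0, p_noise=0.15,
                        gaussian_noise_sd=0.05) if light_augment else AugmentParams()
    defaults = dict(epochs=5, iters_per_epoch=25, batch_size=2, validate_every=1000,
                    augmentation=aug)
    defaults.update(d or {})
    return TrainConfig(seed=seed, folds=folds, **defaults)


@dataclass
class PipelineResult:
    out_dir: str
    scheme_ranking: pd.DataFrame
    reports: Dict[str, MetricsReport]
    summary: dict


def run_pipeline(config: Optional[dict] = None, config_path=None) -> PipelineResult:
    """Run generate → (teacher) → professor → correct → (student) → evaluate.

    ``config`` overrides :data:`DEFAULT_PIPELINE_CONFIG`; seeds for cohort
    generation, folds and every training run derive from the single master
    seed. Held-out test cases never share a patient with any training fold.
    """
    if config_path is not None:
        with open(config_path) as fh:
            config = _merge(config or {}, yaml.safe_load(fh))
    cfg = _merge(DEFAULT_PIPELINE_CONFIG, config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)
    master = int(cfg["seed"])
    ss = np.random.SeedSequence(master)
    sub = {name: int(s.generate_state(1)[0] % (2 ** 31))
           for name, s in zip(["cohort_train", "cohort_test", "cohort_unlabeled",
                               "folds", "train"], ss.spawn(5))}
    presets = preset_configs()
    phantom_cfg = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in cfg["phantom"].items()})
    err = ErrorModel(**cfg["error_model"])
    co = cfg["cohort"]

    timers = {}

    def _phase(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("phase %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timers[name] = time.time() - self.t0
                logger.info("phase %s: %.1fs", name, timers[name])
                return False
        return _T()

    try:
        with _phase("generate"):
            train_manifest = generate_cohort(
                co["n_labeled"], phantom_cfg, err, sub["cohort_train"],
                os.path.join(out_dir, "cohort_train"),
                multi_scan_fraction=co.get("multi_scan_fraction", 0.0),
                tumor_free_fraction=co.get("tumor_free_fraction", 0.0),
                prefix="train")
            test_manifest = generate_cohort(
                co["n_test"], phantom_cfg, err, sub["cohort_test"],
                os.path.join(out_dir, "cohort_test"), prefix="test")
            unlabeled_manifest = None
            if co.get("n_unlabeled", 0):
                unlabeled_manifest = generate_cohort(
                    co["n_unlabeled"], phantom_cfg, err, sub["cohort_unlabeled"],
                    os.path.join(out_dir, "cohort_unlabeled"),
                    intensity_shift_fraction=co.get("intensity_shift_fraction", 0.0),
                    prefix="unlab")
    except Exception as exc:
        raise PhaseError("generate", exc) from exc

    folds = assign_folds(train_manifest["patient_id"].tolist(), int(cfg["folds"]),
                         sub["folds"])

    teacher_result = None
    prof_train_manifest = train_manifest
    if cfg["teacher"]["mode"] == "trained":
        try:
            with _phase("teacher"):
                teacher_result = phase1_teacher(
                    train_manifest, presets[cfg["teacher"]["preset"]],
                    _train_config(cfg["teacher"].get("train"), sub["train"], folds.k),
                    folds, os.path.join(out_dir, "phase1_teacher"))
                prof_train_manifest = teacher_result.manifest
        except PhaseError:
            raise
        except Exception as exc:
            raise PhaseError("teacher", exc) from exc
    elif cfg["teacher"]["mode"] != "simulated":
        raise ConfigurationError(f"unknown teacher mode {cfg['teacher']['mode']!r}")

    # professor phase excludes tumor-free cases (nothing to correct toward)
    prof_manifest = _drop_empty_gt(prof_train_manifest)
    schemes = [SCHEMES[name] for name in cfg["professor"]["schemes"]]
    try:
        with _phase("professor"):
            prof_result = phase2_professor(
                prof_manifest, schemes, presets[cfg["professor"]["preset"]],
                _train_config(cfg["professor"].get("train"), sub["train"] + 1, folds.k),
                folds, os.path.join(out_dir, "phase2_professor"),
                margin=int(cfg["professor"].get("margin", 4)),
                oracle=bool(cfg["professor"].get("oracle", False)))
    except PhaseError:
        raise
    except Exception as exc:
        raise PhaseError("professor", exc) from exc

    student_result = None
    if cfg["student"].get("enabled"):
        try:
            with _phase("student"):
                student_result = phase3_student(
                    train_manifest, unlabeled_manifest, prof_result.selected,
                    presets[cfg["student"]["preset"]],
                    _train_config(cfg["student"].get("train"), sub["train"] + 2, folds.k),
                    os.path.join(out_dir, "phase3_student"))
        except Exception as exc:
            raise PhaseError("student", exc) from exc

    with _phase("evaluate"):
        reports, summary = _evaluate_test(test_manifest, prof_result, student_result,
                                          teacher_result, out_dir)
    summary["timers_s"] = {k: round(v, 2) for k, v in timers.items()}
    summary["selected_scheme"] = prof_result.selected.scheme.name
    summary["scheme_ranking"] = prof_result.ranking[
        ["scheme", "mean_dsc", "sd_dsc"]].to_dict("records")
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return PipelineResult(out_dir, prof_result.ranking, reports, summary)


def _drop_empty_gt(manifest: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for _, row in manifest.iterrows():
        keep.append(pio.read_mask(row["gt_path"]).data.any())
    return manifest[np.asarray(keep, bool)].reset_index(drop=True)


def _evaluate_test(test_manifest: pd.DataFrame, prof_result: ProfessorResult,
                   student_result: Optional[StudentResult],
                   teacher_result: Optional[TeacherResult], out_dir):
    """Teacher vs professor-corrected (vs student) metrics on held-out cases."""
    cases = load_cases(test_manifest)
    teacher_masks, corrected_masks, student_masks = [], [], []
    for case in cases:
        if teacher_result is not None:
            # trained teacher: fold-ensemble majority vote replaces the simulator mask
            rcase = _resample_case(case, teacher_result.models[0].config.target_spacing)
            ch = np.stack([normalize_ct(rcase.volume, teacher_result.stats).data])
            votes = sum((predict(m, ch) > 0).astype(np.int32)
                        for m in teacher_result.models)
            mask = BinaryMask((votes * 2 > len(teacher_result.models)).astype(np.uint8),
                              rcase.volume.spacing)
            if not np.allclose(mask.spacing, case.volume.spacing):
                mask = _match_shape(pio.resample(mask, case.volume.spacing, "nearest"),
                                    case.volume.shape)
            case.teacher = mask
        teacher_masks.append(case.teacher)
        infer_case = Case(case.case_id, case.patient_id, case.volume, None, case.teacher)
        if prof_result.selected.models:
            corrected_masks.append(correct_case(infer_case, prof_result.selected))
        else:  # oracle professor: corrected = exact round trip (needs gt)
            corrected_masks.append(apply_correction(
                case.teacher, encode(case.teacher, case.gt, prof_result.selected.scheme)))
        if student_result is not None:
            rcase = _resample_case(case, student_result.model.config.target_spacing)
            pred = predict(student_result.model,
                           np.stack([normalize_ct(rcase.volume, student_result.stats).data]))
            mask = BinaryMask((pred > 0).astype(np.uint8), rcase.volume.spacing)
            if not np.allclose(mask.spacing, case.volume.spacing):
                mask = _match_shape(pio.resample(mask, case.volume.spacing, "nearest"),
                                    case.volume.shape)
            student_masks.append(mask)

    ids = [c.case_id for c in cases]
    gts = [c.gt for c in cases]
    reports = {
        "teacher": evaluate_cohort(list(zip(ids, teacher_masks, gts))),
        "professor_corrected": evaluate_cohort(list(zip(ids, corrected_masks, gts)),
                                               baseline=teacher_masks),
    }
    if student_masks:
        reports["student"] = evaluate_cohort(list(zip(ids, student_masks, gts)),
                                             baseline=teacher_masks)
    summary = {}
    rep_dir = os.path.join(out_dir, "reports")
    os.makedirs(rep_dir, exist_ok=True)
    for name, rep in reports.items():
        rep.per_case.to_csv(os.path.join(rep_dir, f"{name}_per_case.csv"), index=False)
        summary[name] = {
            "mean_dsc": float(rep.summary.loc["dsc", "mean"]),
            "sd_dsc": float(rep.summary.loc["dsc", "sd"]),
            "mean_hd95": float(rep.summary.loc["hd95", "mean"]),
            "mean_msd": float(rep.summary.loc["msd", "mean"]),
            "mean_sensitivity": float(rep.summary.loc["sensitivity", "mean"]),
            "mean_specificity": float(rep.summary.loc["specificity", "mean"]),
        }
        if rep.paired_test is not None:
            summary[name]["wilcoxon_p_vs_teacher"] = rep.paired_test.p_value
        if "delta_dsc" in rep.summary.index:
            summary[name]["median_dsc_gain"] = float(rep.summary.loc["delta_dsc", "median"])
            summary[name]["mad_dsc_gain"] = float(rep.summary.loc["delta_dsc", "mad"])
    return reports, summary
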