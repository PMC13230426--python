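"""Declarative network/training configuration and the published presets.

The presets reproduce the architecture figures of the teacher/professor/
student networks: target spacings, patch sizes, stage counts, feature
widths, the professor's asymmetric pooling schedule, batch sizes and the
SGD hyperparameters. ``tiny_test`` is a CPU-scale configuration used by the
test suite and the desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

Int3 = Tuple[int, int, int]


class NetConfigError(ValueError):
    """Invalid network configuration (stage/pooling/patch inconsistency)."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture of one 3D encoder-decoder segmentation network."""

    name: str
    n_encoder_stages: int
    n_decoder_stages: int
    base_features: int
    max_features: int
    convs_per_stage: int
    kernel: Int3
    pool_kernels: Tuple[Int3, ...]
    patch_size: Int3
    target_spacing: Tuple[float, float, float]
    in_channels: int = 1
    out_channels: int = 2
    deep_supervision: bool = True
    batch_size: int = 2

    def __post_init__(self):
        if self.n_decoder_stages != self.n_encoder_stages - 1:
            raise NetConfigError(
                f"{self.name}: need n_decoder_stages == n_encoder_stages - 1, got "
                f"{self.n_decoder_stages} vs {self.n_encoder_stages}")
        if len(self.pool_kernels) != self.n_encoder_stages:
            raise NetConfigError(f"{self.name}: need one pool kernel per encoder stage")
        cum = np.prod(np.asarray(self.pool_kernels), axis=0)
        for axis, (p, c) in enumerate(zip(self.patch_size, cum)):
            if p % c != 0:
                raise NetConfigError(
                    f"{self.name}: patch axis {axis} ({p}) not divisible by cumulative "
                    f"pooling {c}")
        if self.base_features < 1 or self.max_features < self.base_features:
            raise NetConfigError(f"{self.name}: bad feature counts")

    def features_at(self, stage: int) -> int:
        return min(self.base_features * (2 ** stage), self.max_features)

    @property
    def stage_features(self) -> List[int]:
        return [self.features_at(s) for s in range(self.n_encoder_stages)]

    def with_channels(self, in_channels: Optional[int] = None,
                      out_channels: Optional[int] = None) -> "NetConfig":
        return replace(self, in_channels=in_channels or self.in_channels,
                       out_channels=out_channels or self.out_channels)


@dataclass(frozen=True)
class AugmentParams:
    """Data-augmentation settings (spatial transforms shared by image and
    label channels; intensity transforms only touch image channels)."""

    rotation_deg: float = 30.0
    scale_range: Tuple[float, float] = (0.7, 1.4)
    p_spatial: float = 0.2
    gaussian_noise_sd: float = 0.1
    p_noise: float = 0.1
    blur_sigma_range: Tuple[float, float] = (0.5, 1.0)
    p_blur: float = 0.2
    brightness_range: Tuple[float, float] = (0.75, 1.25)
    p_brightness: float = 0.15
    contrast_range: Tuple[float, float] = (0.75, 1.25)
    p_contrast: float = 0.15
    mirror_axes: Tuple[int, ...] = (0, 1, 2)
    p_mirror: float = 0.5

    def __post_init__(self):
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad scale_range {self.scale_range}")

    @classmethod
    def disabled(cls) -> "AugmentParams":
        return cls(p_spatial=0.0, p_noise=0.0, p_blur=0.0, p_brightness=0.0,
                   p_contrast=0.0, p_mirror=0.0, mirror_axes=())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Published full-scale defaults; tests override downwards."""

    momentum: float = 0.99
    nesterov: bool = True
    weight_decay: float = 3e-5
    initial_lr: float = 0.01
    poly_exponent: float = 0.9
    epochs: int = 1000
    iters_per_epoch: int = 250
    batch_size: int = 2
    folds: int = 5
    seed: int = 0
    validate_every: int = 50
    foreground_oversample: float = 1.0 / 3.0
    augmentation: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self):
        if min(self.epochs, self.iters_per_epoch, self.batch_size, self.folds) < 1:
            raise ValueError("epochs, iters, batch and folds must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")

    def lr_at(self, step: int) -> float:
        """Polynomial decay lr0 * (1 - t/T)^exponent over all optimizer steps."""
        total = self.epochs * self.iters_per_epoch
        return self.initial_lr * (1.0 - step / total) ** self.poly_exponent


def preset_configs() -> Dict[str, NetConfig]:
    """The published architecture presets plus a CPU-scale test config.

    Spacings/patches/stages/channels and the professor's pooling schedule
    follow the printed configurations; pooling schedules for the cascade
    networks are not printed and follow the usual anisotropy-aware pattern
    (z pooled less often than in-plane axes).
    """
    cascade_kw = dict(n_encoder_stages=6, n_decoder_stages=5, base_features=32,
                      max_features=320, convs_per_stage=2, kernel=(3, 3, 3),
                      batch_size=2)
    near_iso_pools = ((1, 1, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2))
    aniso_pools = ((1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2))
    presets = [
        NetConfig(name="teacher_lowres", patch_size=(96, 160, 160),
                  target_spacing=(2.85, 1.45, 1.45), pool_kernels=near_iso_pools,
                  in_channels=1, **cascade_kw),
        NetConfig(name="teacher_fullres", patch_size=(64, 192, 160),
                  target_spacing=(2.0, 0.71, 0.71), pool_kernels=aniso_pools,
                  in_channels=2, **cascade_kw),  # image + upsampled low-res segmentation
        NetConfig(name="professor", n_encoder_stages=5, n_decoder_stages=4,
                  base_features=32, max_features=320, convs_per_stage=2,
                  kernel=(3, 3, 3),
                  pool_kernels=((1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2)),
                  patch_size=(24, 64, 80), target_spacing=(2.0, 0.70, 0.70),
                  in_channels=2, out_channels=3, batch_size=3),
        NetConfig(name="student_lowres", patch_size=(64, 192, 192),
                  target_spacing=(2.53, 1.30, 1.30), pool_kernels=near_iso_pools,
                  in_channels=1, **cascade_kw),
        NetConfig(name="student_fullres", patch_size=(48, 192, 192),
                  target_spacing=(2.0, 0.76, 0.76), pool_kernels=aniso_pools,
                  in_channels=2, **cascade_kw),
        NetConfig(name="tiny_test", n_encoder_stages=3, n_decoder_stages=2,
                  base_features=8, max_features=32, convs_per_stage=2,
                  kernel=(3, 3, 3),
                  pool_kernels=((1, 1, 1), (2, 2, 2), (2, 2, 2)),
                  patch_size=(24, 24, 24), target_spacing=(1.5, 1.5, 1.5),
                  in_channels=1, out_channels=2, batch_size=2),
    ]
    return {p.name: p for p in presets}
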