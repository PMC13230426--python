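"""3D U-Net built from the autodiff primitives.

Encoder stages downsample with strided convolutions (per-axis pool kernels),
the decoder upsamples with nearest-neighbour interpolation followed by
convolutions over the concatenated skip connection. With deep supervision a
1×1×1 segmentation head is attached at every decoder resolution.
"""

from __future__ import annotations

import pickle
from typing import List, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import NetConfig, NetConfigError


def _he_init(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class ConvBlock:
    """conv -> instance norm -> leaky ReLU, with optional stride."""

    def __init__(self, rng, c_in: int, c_out: int, kernel, stride=(1, 1, 1)):
        self.stride = tuple(int(s) for s in stride)
        self.weight = ad.parameter(_he_init(rng, (c_out,) + (c_in,) + tuple(kernel)))
        self.bias = ad.parameter(np.zeros(c_out, dtype=np.float32))
        self.gamma = ad.parameter(np.ones(c_out, dtype=np.float32))
        self.beta = ad.parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.conv3d(x, self.weight, self.bias, self.stride)
        x = ad.instance_norm(x, self.gamma, self.beta)
        return ad.leaky_relu(x)

    @property
    def params(self):
        return [self.weight, self.bias, self.gamma, self.beta]


class SegHead:
    """1×1×1 convolution producing per-voxel class scores."""

    def __init__(self, rng, c_in: int, n_classes: int):
        self.weight = ad.parameter(_he_init(rng, (n_classes, c_in, 1, 1, 1)))
        self.bias = ad.parameter(np.zeros(n_classes, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)

    @property
    def params(self):
        return [self.weight, self.bias]


class UNet3D:
    """Configurable 3D U-Net; see :class:`NetConfig` for the architecture knobs."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        feats = config.stage_features
        self.encoder: List[List[ConvBlock]] = []
        c_prev = config.in_channels
        for s in range(config.n_encoder_stages):
            blocks = [ConvBlock(rng, c_prev, feats[s], config.kernel,
                                stride=config.pool_kernels[s])]
            for _ in range(config.convs_per_stage - 1):
                blocks.append(ConvBlock(rng, feats[s], feats[s], config.kernel))
            self.encoder.append(blocks)
            c_prev = feats[s]

        self.decoder: List[List[ConvBlock]] = []
        self.heads: List[SegHead] = []
        # decoder stage d refines encoder scale d using the map from scale d+1
        for d in range(config.n_decoder_stages - 1, -1, -1):
            c_in = feats[d + 1] + feats[d]
            blocks = [ConvBlock(rng, c_in, feats[d], config.kernel)]
            for _ in range(config.convs_per_stage - 1):
                blocks.append(ConvBlock(rng, feats[d], feats[d], config.kernel))
            self.decoder.append(blocks)
            self.heads.append(SegHead(rng, feats[d], config.out_channels))

    # ------------------------------------------------------------------
    @property
    def params(self) -> List[Tensor]:
        out = []
        for stage in self.encoder + self.decoder:
            for block in stage:
                out.extend(block.params)
        for head in self.heads:
            out.extend(head.params)
        return out

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise NetConfigError(
                f"expected (N, {self.config.in_channels}, D, H, W) input, got {x.shape}")
        cum = np.prod(np.asarray(self.config.pool_kernels), axis=0)
        for axis, (n, c) in enumerate(zip(x.shape[2:], cum)):
            if n % c != 0:
                raise NetConfigError(
                    f"input axis {axis} ({n}) not divisible by cumulative pooling {c}")

    def forward(self, x: np.ndarray) -> List[Tensor]:
        """Score maps, finest scale first; one per decoder resolution when
        deep supervision is on, otherwise just the full-resolution head."""
        self._check_input(x)
        t = Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        for blocks in self.encoder:
            for b in blocks:
                t = b(t)
            skips.append(t)

        outputs: List[Tensor] = []
        for i, blocks in enumerate(self.decoder):
            d = self.config.n_decoder_stages - 1 - i  # encoder scale being refined
            t = ad.upsample_nearest(t, self.config.pool_kernels[d + 1])
            t = ad.concat(t, skips[d])
            for b in blocks:
                t = b(t)
            outputs.append(self.heads[i](t))
        outputs = outputs[::-1]  # finest first
        if not self.config.deep_supervision:
            outputs = outputs[:1]
        return outputs

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        return {"config": self.config, "params": [p.data.copy() for p in self.params]}

    def load_state(self, state: dict) -> None:
        params = self.params
        if len(state["params"]) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for p, arr in zip(params, state["params"]):
            if p.data.shape != arr.shape:
                raise ValueError("checkpoint tensor shape mismatch")
            p.data = arr.astype(np.float32).copy()

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path) -> "UNet3D":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["config"])
        model.load_state(state)
        return model


def build_unet(config: NetConfig, seed: int = 0) -> UNet3D:
    """Build a seeded :class:`UNet3D` from a validated config."""
    return UNet3D(config, seed=seed)


def deep_supervision_weights(n_scales: int) -> np.ndarray:
    """Per-scale loss weights: halve per coarser scale, zero the coarsest,
    normalized to sum 1 (single-scale nets get weight 1)."""
    if n_scales == 1:
        return np.ones(1)
    w = 0.5 ** np.arange(n_scales)
    w[-1] = 0.0
    return w / w.sum()
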