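"""Network configs/presets, loss arithmetic, augmentation and train/predict contracts."""

import dataclasses
import math

import numpy as np
import pytest

from profcorrect.nets import (AugmentParams, DivergenceError, NetConfig, NetConfigError,
                              Sample, TrainConfig, augment, build_unet, combined_loss,
                              dice_ce_with_grad, loss_components, predict,
                              preset_configs, train)
from profcorrect.nets.unet import deep_supervision_weights

TINY = preset_configs()["tiny_test"]


class TestNetConfig:
    def test_decoder_stage_constraint(self):
        with pytest.raises(NetConfigError):
            dataclasses.replace(TINY, n_decoder_stages=3)

    def test_patch_pooling_divisibility(self):
        with pytest.raises(NetConfigError, match="divisible"):
            dataclasses.replace(TINY, patch_size=(24, 24, 30),
                                pool_kernels=((1, 1, 1), (2, 2, 2), (2, 2, 2)))
        bad_pool16 = ((1, 1, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))
        with pytest.raises(NetConfigError):
            NetConfig(name="bad", n_encoder_stages=5, n_decoder_stages=4,
                      base_features=8, max_features=32, convs_per_stage=2,
                      kernel=(3, 3, 3), pool_kernels=bad_pool16,
                      patch_size=(24, 24, 24), target_spacing=(1, 1, 1))

    def test_feature_cap(self):
        cfg = preset_configs()["teacher_lowres"]
        assert cfg.stage_features == [32, 64, 128, 256, 320, 320]


class TestPresets:
    """Field-by-field fidelity to the published architecture figures."""

    def setup_method(self):
        self.p = preset_configs()

    def test_teacher_lowres(self):
        c = self.p["teacher_lowres"]
        assert c.target_spacing == (2.85, 1.45, 1.45)
        assert c.patch_size == (96, 160, 160)
        assert (c.n_encoder_stages, c.n_decoder_stages) == (6, 5)
        assert (c.base_features, c.max_features) == (32, 320)
        assert c.convs_per_stage == 2 and c.kernel == (3, 3, 3)
        assert c.batch_size == 2

    def test_teacher_fullres(self):
        c = self.p["teacher_fullres"]
        assert c.target_spacing == (2.0, 0.71, 0.71)
        assert c.patch_size == (64, 192, 160)
        assert c.in_channels == 2  # image + low-res cascade segmentation

    def test_professor(self):
        c = self.p["professor"]
        assert c.target_spacing == (2.0, 0.70, 0.70)
        assert c.patch_size == (24, 64, 80)
        assert (c.n_encoder_stages, c.n_decoder_stages) == (5, 4)
        assert c.pool_kernels == ((1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2))
        assert c.in_channels == 2  # dual channel: CT + teacher mask
        assert c.batch_size == 3

    def test_professor_pooling_counts(self):
        """Two poolings along z, four along y/x."""
        pools = np.prod(np.asarray(self.p["professor"].pool_kernels), axis=0)
        assert pools.tolist() == [4, 16, 16]

    def test_student(self):
        lo, hi = self.p["student_lowres"], self.p["student_fullres"]
        assert lo.target_spacing == (2.53, 1.30, 1.30) and lo.patch_size == (64, 192, 192)
        assert hi.target_spacing == (2.0, 0.76, 0.76) and hi.patch_size == (48, 192, 192)
        assert (hi.base_features, hi.max_features) == (32, 320)

    def test_tiny_builds_and_runs_fast(self):
        model = build_unet(TINY, seed=0)
        out = model.forward(np.zeros((1, 1, 24, 24, 24), np.float32))
        assert out[0].data.shape == (1, 2, 24, 24, 24)

    def test_optimizer_constants(self):
        tc = TrainConfig()
        assert (tc.momentum, tc.nesterov, tc.weight_decay) == (0.99, True, 3e-5)
        assert tc.initial_lr == 0.01
        assert (tc.epochs, tc.iters_per_epoch, tc.validate_every) == (1000, 250, 50)
        assert (tc.augmentation.rotation_deg, tc.augmentation.scale_range) == (30.0, (0.7, 1.4))


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        target = np.zeros((1, 4, 4, 4), np.int64)
        target[0, 1:3, 1:3, 1:3] = 1
        logits = np.zeros((1, 2, 4, 4, 4), np.float32)
        logits[0, 1] = np.where(target[0] == 1, 20.0, -20.0)
        logits[0, 0] = -logits[0, 1]
        dice, ce = loss_components(logits, target)
        assert ce == pytest.approx(0.0, abs=1e-6)
        assert dice == pytest.approx(0.0, abs=1e-3)

    def test_uniform_scores_ce_is_ln2(self):
        logits = np.zeros((1, 2, 3, 3, 3), np.float32)
        target = np.zeros((1, 3, 3, 3), np.int64)
        target[0, 0, 0, 0] = 1
        _, ce = loss_components(logits, target)
        assert ce == pytest.approx(math.log(2))

    def test_two_voxel_hand_arithmetic(self):
        # voxels: logits give p1 = [0.7311, 0.5]; target = [1, 0]
        logits = np.zeros((1, 2, 1, 1, 2), np.float32)
        logits[0, 1, 0, 0, 0] = 1.0  # p(fg) = sigmoid(1)
        target = np.zeros((1, 1, 1, 2), np.int64)
        target[0, 0, 0, 0] = 1
        p1 = 1 / (1 + math.exp(-1))
        eps = 1e-5
        dice_hand = 1 - 2 * p1 / (p1 + 0.5 + 1 + eps)
        ce_hand = -(math.log(p1) + math.log(0.5)) / 2
        loss = combined_loss([logits], target)
        assert loss == pytest.approx(0.5 * dice_hand + 0.5 * ce_hand, rel=1e-5)

    def test_permutation_invariance(self, rng):
        logits = rng.normal(size=(1, 3, 2, 2, 2)).astype(np.float32)
        target = rng.integers(0, 3, (1, 2, 2, 2))
        perm = rng.permutation(8)
        lp = logits.reshape(1, 3, 8)[:, :, perm].reshape(1, 3, 2, 2, 2)
        tp = target.reshape(1, 8)[:, perm].reshape(1, 2, 2, 2)
        assert combined_loss([logits], target) == pytest.approx(
            combined_loss([lp], tp), rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float64)
        target = rng.integers(0, 2, (1, 2, 2, 2))
        _, grad = dice_ce_with_grad(logits, target)
        eps = 1e-5
        for idx in [(0, 0, 0, 0, 0), (0, 1, 1, 1, 1), (0, 0, 1, 0, 1)]:
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (dice_ce_with_grad(lp, target)[0] - dice_ce_with_grad(lm, target)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-6)

    def test_deep_supervision_weights(self):
        w = deep_supervision_weights(4)
        assert w[-1] == 0.0
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > w[1] > w[2]


class TestAugment:
    def test_disabled_is_identity(self, rng):
        ch = rng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        tg = rng.integers(0, 2, (6, 6, 6))
        out_ch, out_tg = augment(ch, tg, AugmentParams.disabled(), seed=0)
        assert np.array_equal(out_ch, ch) and np.array_equal(out_tg, tg)

    def test_mirror_involution(self, rng):
        params = AugmentParams(p_spatial=0, p_noise=0, p_blur=0, p_brightness=0,
                               p_contrast=0, mirror_axes=(0,), p_mirror=1.0)
        ch = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        tg = rng.integers(0, 2, (4, 4, 4))
        once = augment(ch, tg, params, seed=1)
        twice = augment(once[0], once[1], params, seed=2)
        assert np.array_equal(twice[0], ch) and np.array_equal(twice[1], tg)

    def test_labels_stay_binary_under_spatial(self, rng):
        params = AugmentParams(p_spatial=1.0, p_noise=0, p_blur=0, p_brightness=0,
                               p_contrast=0, p_mirror=0)
        ch = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        ch[1] = (ch[1] > 0)
        tg = rng.integers(0, 3, (8, 8, 8))
        out_ch, out_tg = augment(ch, tg, params, seed=3, intensity_channels=[0])
        assert set(np.unique(out_ch[1])) <= {0.0, 1.0}   # mask channel nearest-interp
        assert set(np.unique(out_tg)) <= {0, 1, 2}

    def test_intensity_never_touches_mask_channel(self, rng):
        params = AugmentParams(p_spatial=0, p_mirror=0, p_noise=1.0, p_blur=1.0,
                               p_brightness=1.0, p_contrast=1.0)
        ch = np.stack([rng.normal(size=(5, 5, 5)).astype(np.float32),
                       rng.integers(0, 2, (5, 5, 5)).astype(np.float32)])
        out_ch, _ = augment(ch, None, params, seed=4, intensity_channels=[0])
        assert np.array_equal(out_ch[1], ch[1])
        assert not np.array_equal(out_ch[0], ch[0])

    def test_seeded_determinism(self, rng):
        ch = rng.normal(size=(1, 6, 6, 6)).astype(np.float32)
        tg = rng.integers(0, 2, (6, 6, 6))
        a = augment(ch, tg, AugmentParams(), seed=7)
        b = augment(ch, tg, AugmentParams(), seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def _toy_config():
    return dataclasses.replace(TINY, name="toy", n_encoder_stages=2, n_decoder_stages=1,
                               base_features=4, max_features=8,
                               pool_kernels=((1, 1, 1), (2, 2, 2)),
                               patch_size=(16, 16, 16))


def _toy_samples(n=2, shape=(16, 16, 16)):
    """Linearly separable toy: foreground is simply intensity > 0."""
    rng = np.random.default_rng(0)
    samples = []
    for i in range(n):
        tg = np.zeros(shape, np.int64)
        lo = 4 + i
        tg[lo:lo + 6, lo:lo + 6, lo:lo + 6] = 1
        ch = np.where(tg > 0, 1.0, -1.0) + rng.normal(0, 0.1, shape)
        samples.append(Sample(ch[None].astype(np.float32), tg, f"toy{i}"))
    return samples


class TestTrain:
    def test_smoke_history_and_lr_schedule(self):
        cfg = TrainConfig(epochs=2, iters_per_epoch=3, batch_size=2, folds=2, seed=0,
                          augmentation=AugmentParams.disabled(), validate_every=10 ** 9)
        model = build_unet(_toy_config(), seed=0)
        hist = train(model, _toy_samples(4), cfg)
        assert len(hist) == 2
        assert np.isfinite(hist["loss"]).all()
        # polynomial decay hits zero at the end of the budget
        assert cfg.lr_at(cfg.epochs * cfg.iters_per_epoch) == pytest.approx(0.0)
        assert cfg.lr_at(0) == pytest.approx(cfg.initial_lr)

    def test_deterministic_same_seed(self):
        cfg = TrainConfig(epochs=1, iters_per_epoch=4, batch_size=2, folds=2, seed=3,
                          augmentation=AugmentParams.disabled(), validate_every=10 ** 9)
        h1 = train(build_unet(_toy_config(), seed=1), _toy_samples(3), cfg)
        h2 = train(build_unet(_toy_config(), seed=1), _toy_samples(3), cfg)
        assert np.array_equal(h1["loss"].to_numpy(), h2["loss"].to_numpy())

    def test_loss_halves_on_separable_toy_within_5_epochs(self):
        cfg = TrainConfig(epochs=5, iters_per_epoch=10, batch_size=2, folds=2, seed=0,
                          augmentation=AugmentParams.disabled(), validate_every=10 ** 9)
        model = build_unet(_toy_config(), seed=0)
        hist = train(model, _toy_samples(2), cfg)
        assert hist["loss"].iloc[-1] <= 0.5 * hist["loss"].iloc[0]

    def test_empty_dataset_rejected(self):
        from profcorrect.nets import DataError
        with pytest.raises(DataError):
            train(build_unet(_toy_config()), [], TrainConfig(epochs=1, iters_per_epoch=1))


class TestPredict:
    def test_small_volume_padded_and_unpadded(self):
        model = build_unet(_toy_config(), seed=0)
        out = predict(model, np.zeros((1, 10, 11, 12), np.float32))
        assert out.shape == (10, 11, 12)
        assert set(np.unique(out)) <= {0, 1}

    def test_large_volume_tiled(self):
        model = build_unet(_toy_config(), seed=0)
        out = predict(model, np.zeros((1, 20, 24, 20), np.float32))
        assert out.shape == (20, 24, 20)

    def test_channel_mismatch_rejected(self):
        model = build_unet(_toy_config(), seed=0)
        with pytest.raises(NetConfigError):
            predict(model, np.zeros((3, 16, 16, 16), np.float32))

    def test_professor_outputs_restricted_to_class_range(self):
        cfg = dataclasses.replace(_toy_config(), in_channels=2, out_channels=3)
        model = build_unet(cfg, seed=0)
        out = predict(model, np.zeros((2, 16, 16, 16), np.float32))
        assert set(np.unique(out)) <= {0, 1, 2}

    def test_trained_toy_model_segments(self):
        cfg = TrainConfig(epochs=4, iters_per_epoch=10, batch_size=2, folds=2, seed=0,
                          augmentation=AugmentParams.disabled(), validate_every=10 ** 9)
        model = build_unet(_toy_config(), seed=0)
        samples = _toy_samples(2)
        train(model, samples, cfg)
        pred = predict(model, samples[0].channels)
        inter = np.logical_and(pred > 0, samples[0].target > 0).sum()
        d = 2 * inter / max(1, (pred > 0).sum() + (samples[0].target > 0).sum())
        assert d > 0.7


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        from profcorrect.nets import UNet3D
        model = build_unet(_toy_config(), seed=5)
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
        ref = model.forward(x)[0].data
        model.save(tmp_path / "m.pkl")
        back = UNet3D.load(tmp_path / "m.pkl")
        assert np.array_equal(back.forward(x)[0].data, ref)


class TestMirrorTTA:
    def test_prediction_equivariant_to_mirroring(self, rng):
        """Averaging probabilities over all axis flips makes the prediction
        commute with mirroring (group averaging), for any model weights."""
        from profcorrect.nets import predict_probs
        model = build_unet(_toy_config(), seed=2)
        x = rng.normal(size=(1, 16, 16, 16)).astype(np.float32)  # one full patch
        p = predict_probs(model, x, mirror_tta=True)
        for axis in (0, 1, 2):
            xm = np.ascontiguousarray(np.flip(x, axis=axis + 1))
            pm = predict_probs(model, xm, mirror_tta=True)
            assert np.allclose(pm, np.flip(p, axis=axis + 1), atol=1e-6)


class TestCascadeStage2:
    def test_channels_combine_ct_and_upsampled_lowres_seg(self, rng):
        from profcorrect.grids import BinaryMask, Volume
        from profcorrect.orchestrate import Case, cascade_stage2_channels
        from profcorrect.preprocess import NormStats
        vol = Volume(rng.normal(60, 10, (16, 16, 16)).astype(np.float32),
                     spacing=(1.0, 1.0, 1.0))
        case = Case("c0", "p0", vol)
        lowres = BinaryMask(rng.integers(0, 2, (8, 8, 8)).astype(np.uint8),
                            spacing=(2.0, 2.0, 2.0))
        ch = cascade_stage2_channels(case, lowres,
                                     NormStats(clip_lo=0, clip_hi=120, mean=60, sd=10))
        assert ch.shape == (2, 16, 16, 16)
        assert set(np.unique(ch[1])) <= {0.0, 1.0}  # seg channel stays one-hot
        # nearest upsampling: each low-res voxel becomes a 2x2x2 block
        assert ch[1, 0, 0, 0] == ch[1, 1, 1, 1] == lowres.data[0, 0, 0]
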