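import numpy as np
import pytest

from fociquant.io import Channel, PlaneImage, SemanticMask
from fociquant.unet import (
    AugmentationSpec,
    UnetConfig,
    augment,
    build_unet,
    dihedral_transform,
    load_model,
    predict_mask,
    save_model,
    soft_jaccard_loss,
    train,
)

TINY = UnetConfig(input_size=(64, 64), depth=2, base_filters=4, downsample_input=True,
                  batch_size=4, epochs=3, learning_rate=1e-3, seed=0)


class TestSoftJaccardLoss:
    def test_identity_is_zero(self):
        t = (np.random.default_rng(0).uniform(size=(32, 32)) > 0.6).astype(float)
        assert soft_jaccard_loss(t, t) <= 1e-5

    def test_disjoint_is_one(self):
        t = np.zeros((16, 16))
        t[:8] = 1.0
        assert soft_jaccard_loss(1.0 - t, t) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_against_quarter_foreground(self):
        # pred 0.5 everywhere, 25% foreground: 1 − 0.125/(0.5+0.25−0.125) = 0.8
        t = np.zeros((20, 20))
        t[:10, :10] = 1.0
        p = np.full((20, 20), 0.5)
        assert soft_jaccard_loss(p, t) == pytest.approx(0.8, abs=1e-6)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=(8, 8))
            t = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
            assert -1e-6 <= soft_jaccard_loss(p, t) <= 1.0 + 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_jaccard_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAugmentation:
    def test_all_transforms_invertible(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(size=(6, 6))
        for k in range(8):
            back = dihedral_transform(dihedral_transform(arr, k), k, inverse=True)
            np.testing.assert_array_equal(back, arr)

    def test_mask_area_preserved(self):
        rng = np.random.default_rng(2)
        img = PlaneImage(rng.uniform(1, 100, size=(16, 16)), 0.2)
        msk = SemanticMask((rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8), 0.2)
        for seed in range(10):
            _, m2 = augment(img, msk, AugmentationSpec(), np.random.default_rng(seed))
            assert m2.raster.sum() == msk.raster.sum()

    def test_contrast_scales_intensities(self):
        msk = SemanticMask(np.zeros((8, 8), dtype=np.uint8), 0.2)
        img = PlaneImage(np.full((8, 8), 100.0), 0.2)
        spec = AugmentationSpec(dihedral=False, contrast_factors=(0.8,))
        seen = set()
        for seed in range(30):
            out, _ = augment(img, msk, spec, np.random.default_rng(seed))
            seen.add(round(float(out.raster[0, 0]), 6))
        assert seen == {100.0, 80.0}  # identity draw and the 0.8 draw
        # a >1 factor saturates at the original maximum
        img2 = PlaneImage(np.where(np.arange(64).reshape(8, 8) < 32, 50.0, 100.0), 0.2)
        bright = AugmentationSpec(dihedral=False, contrast_factors=(1.2,))
        maxima, minima = set(), set()
        for seed in range(30):
            out, _ = augment(img2, msk, bright, np.random.default_rng(seed))
            maxima.add(float(out.raster.max()))
            minima.add(float(out.raster.min()))
        assert maxima == {100.0} and minima == {50.0, 60.0}

    def test_identity_draw_leaves_pair_unchanged(self):
        img = PlaneImage(np.arange(16, dtype=float).reshape(4, 4), 0.2)
        msk = SemanticMask(np.eye(4, dtype=np.uint8), 0.2)
        spec = AugmentationSpec(dihedral=False, contrast_factors=())
        out_img, out_msk = augment(img, msk, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(out_img.raster, img.raster)
        np.testing.assert_array_equal(out_msk.raster, msk.raster)


class TestBuildAndPredict:
    def test_output_shape_and_sigmoid_range(self):
        model = build_unet(TINY)
        out = model.network.forward(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert out.shape == (1, 1, 64, 64)
        assert np.all((out > 0) & (out < 1))

    def test_same_seed_same_parameters(self):
        a, b = build_unet(TINY), build_unet(TINY)
        assert a.network.n_parameters() == b.network.n_parameters()
        for ka, kb in zip(a.network.state_dict().values(), b.network.state_dict().values()):
            np.testing.assert_array_equal(ka, kb)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UnetConfig(input_size=(100, 100), depth=4)

    def test_untrained_predict_rejected(self):
        model = build_unet(TINY)
        with pytest.raises(ValueError, match="untrained"):
            predict_mask(model, PlaneImage(np.zeros((64, 64)), 0.2))

    def test_nuclei_mode_restores_input_geometry(self, small_scene_pairs):
        cfg = UnetConfig(input_size=(32, 32), depth=2, base_filters=4, batch_size=4,
                         epochs=1, seed=0)
        model = build_unet(cfg, Channel.DAPI)
        model = train(model, small_scene_pairs[:4], small_scene_pairs[4:6], cfg)
        big = PlaneImage(np.random.default_rng(0).uniform(0, 100, (96, 96)), 0.5)
        mask = predict_mask(model, big)
        assert mask.shape == (96, 96) and mask.pixel_size_um == 0.5


class TestTraining:
    def test_one_epoch_history_and_serialization(self, small_scene_pairs, tmp_path):
        cfg = UnetConfig(input_size=(64, 64), depth=2, base_filters=4, batch_size=2,
                         epochs=1, seed=1)
        model = build_unet(cfg, Channel.DAPI)
        model = train(model, small_scene_pairs[:2], small_scene_pairs[2:3], cfg)
        assert len(model.training_history) == 1
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        probe = small_scene_pairs[3][0]
        np.testing.assert_array_equal(
            predict_mask(model, probe).raster, predict_mask(back, probe).raster
        )

    def test_training_beats_untrained_validation_loss(self, small_scene_pairs):
        from fociquant.unet import _eval_loss, _prepare_pairs

        cfg = UnetConfig(input_size=(64, 64), depth=2, base_filters=8, batch_size=4,
                         epochs=8, learning_rate=1e-3, seed=3)
        model = build_unet(cfg, Channel.DAPI)
        va_imgs, va_msks = _prepare_pairs(small_scene_pairs[6:], cfg)
        untrained = _eval_loss(model.network, va_imgs, va_msks, cfg.batch_size)
        model = train(model, small_scene_pairs[:6], small_scene_pairs[6:], cfg)
        best = min(h["val_loss"] for h in model.training_history)
        assert best < untrained

    def test_checkpoint_keeps_argmin_epoch_weights(self, small_scene_pairs):
        # train twice with the same seed: the restored weights must reproduce
        # the minimum recorded validation loss exactly
        from fociquant.unet import _eval_loss, _prepare_pairs

        cfg = UnetConfig(input_size=(64, 64), depth=2, base_filters=4, batch_size=4,
                         epochs=5, seed=2)
        model = build_unet(cfg, Channel.DAPI)
        model = train(model, small_scene_pairs[:5], small_scene_pairs[5:7], cfg)
        va_imgs, va_msks = _prepare_pairs(small_scene_pairs[5:7], cfg)
        reeval = _eval_loss(model.network, va_imgs, va_msks, cfg.batch_size)
        assert reeval == pytest.approx(min(h["val_loss"] for h in model.training_history), abs=1e-9)

    def test_empty_sets_rejected(self, small_scene_pairs):
        model = build_unet(TINY)
        with pytest.raises(ValueError):
            train(model, [], small_scene_pairs[:1], TINY)
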