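"""Generator/discriminator contracts, composite loss, and toy training."""

import numpy as np
import pytest

from qmapsr import phantom as ph
from qmapsr import acquisition as acq
from qmapsr.srgan import (LossWeights, SRGANConfig, SRGANSuperResolver,
                          build_discriminator, build_feature_extractor,
                          build_generator, loss_adversarial, loss_mae,
                          loss_perceptual, loss_total, super_resolve)

TOY = SRGANConfig(base_channels=8, n_residual_blocks=2,
                  disc_channel_plan=(8, 8, 16, 16, 16, 16, 16, 16),
                  feat_channel_plan=(4, 4, 8, 8), batch_size=2, rng_seed=0)


class TestGenerator:
    def test_upsamples_by_factor_two_with_tanh_range(self):
        gen = build_generator(TOY)
        x = np.random.default_rng(0).normal(size=(2, 1, 16, 16))
        y = gen.forward(x, train=False)
        assert y.shape == (2, 1, 32, 32)
        assert np.all(np.abs(y) <= 1.0)

    @pytest.mark.parametrize("size", [16, 24, 32])
    def test_fully_convolutional_size_scaling(self, size):
        gen = build_generator(TOY)
        x = np.random.default_rng(1).normal(size=(1, 1, size, size))
        assert gen.forward(x, train=False).shape == (1, 1, 2 * size, 2 * size)

    def test_factor_four_uses_cascaded_shuffles(self):
        cfg = SRGANConfig(base_channels=8, n_residual_blocks=1,
                          upsample_factor=4, feat_channel_plan=(4, 4, 8, 8))
        gen = build_generator(cfg)
        x = np.random.default_rng(2).normal(size=(1, 1, 8, 8))
        assert gen.forward(x, train=False).shape == (1, 1, 32, 32)

    def test_non_power_of_two_factor_rejected(self):
        with pytest.raises(ValueError):
            SRGANConfig(upsample_factor=3)


class TestDiscriminator:
    def test_outputs_probabilities_per_image(self):
        disc = build_discriminator(TOY)
        x = np.random.default_rng(3).normal(size=(4, 1, 32, 32))
        p = disc.forward(x, train=False)
        assert p.shape == (4, 1)
        assert np.all((p > 0) & (p < 1))

    def test_deterministic_in_eval_mode(self):
        disc = build_discriminator(TOY)
        x = np.random.default_rng(4).normal(size=(1, 1, 32, 32))
        xx = np.concatenate([x, x])
        p = disc.forward(xx, train=False)
        assert p[0] == pytest.approx(p[1])

    def test_seeded_construction_reproducible(self):
        x = np.random.default_rng(5).normal(size=(2, 1, 32, 32))
        a = build_discriminator(TOY).forward(x, train=False)
        b = build_discriminator(TOY).forward(x, train=False)
        assert np.array_equal(a, b)


class TestLosses:
    def test_mae_trivial_and_bruteforce(self):
        a = np.zeros((1, 2, 2))
        assert loss_mae(a, a) == 0.0
        assert loss_mae(a + 4.0, a) == 4.0
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(1, 8, 8)), rng.normal(size=(1, 8, 8))
        brute = sum(abs(x[0, i, j] - y[0, i, j])
                    for i in range(8) for j in range(8)) / 64
        assert loss_mae(x, y) == pytest.approx(brute, rel=1e-12)
        with pytest.raises(ValueError):
            loss_mae(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_adversarial_trivial_and_bruteforce(self):
        assert loss_adversarial(np.ones(4)) == pytest.approx(0.0, abs=1e-5)
        assert loss_adversarial(np.full(2, np.exp(-1.0))) == pytest.approx(2.0)
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.99, size=6)
        assert loss_adversarial(p) == pytest.approx(-sum(np.log(v) for v in p))

    def test_perceptual_trivial_and_bruteforce(self):
        f = np.ones((1, 1, 1))
        assert loss_perceptual(f, f) == 0.0
        assert loss_perceptual(f * 3, f) == 4.0
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(3, 4, 4)), rng.normal(size=(3, 4, 4))
        brute = sum((a[c, i, j] - b[c, i, j]) ** 2 for c in range(3)
                    for i in range(4) for j in range(4)) / (3 * 4 * 4)
        assert loss_perceptual(a, b) == pytest.approx(brute, rel=1e-12)

    def test_total_weighting(self):
        assert loss_total(1.0, 2.0, 3.0) == pytest.approx(1.002006)
        assert loss_total(0.0, 0.0, 0.0) == 0.0
        assert loss_total(1.0, 1.0, 1.0, LossWeights(1, 1, 1)) == 3.0
        w = LossWeights()
        assert (w.w_mae, w.w_gan, w.w_vgg) == (1.0, 1e-3, 2e-6)

    def test_default_batch_size_is_eight(self):
        assert SRGANConfig().batch_size == 8


class TestTraining:
    def test_pure_l1_fits_constant_pair(self):
        """With adversarial and perceptual weights zero the model is plain
        L1 regression and drives a constant-image pair below 1e-3 within
        500 iterations."""
        lr_img = np.full((1, 8, 8), 0.2)
        hr_img = np.full((1, 16, 16), -0.3)
        model = SRGANSuperResolver(
            base_channels=8, n_residual_blocks=1, batch_size=1, epochs=500,
            max_iterations=500, rng_seed=0, learning_rate=1e-2,
            lr_decay_interval=100, loss_weights=LossWeights(1.0, 0.0, 0.0))
        model.fit(lr_img, hr_img)
        sm = model.log_.smoothed_total(window=50)
        assert sm[-1] < sm[0]
        assert model.log_.l_total[-1] < 1e-3

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(9)
        lr_img = rng.uniform(-1, 1, size=(4, 8, 8))
        hr_img = rng.uniform(-1, 1, size=(4, 16, 16))

        def run():
            m = SRGANSuperResolver(
                base_channels=4, n_residual_blocks=1, batch_size=2, epochs=10,
                max_iterations=20, rng_seed=5,
                disc_channel_plan=(4, 4, 4, 4, 8, 8, 8, 8),
                feat_channel_plan=(2, 2, 4, 4))
            m.fit(lr_img, hr_img)
            return m
        a, b = run(), run()
        for pa, pb in zip(a.generator_.params, b.generator_.params):
            assert np.array_equal(pa, pb)
        assert a.log_.l_total == b.log_.l_total

    def test_shape_validation(self):
        model = SRGANSuperResolver(rng_seed=0)
        with pytest.raises(ValueError):
            model.fit(np.zeros((2, 8, 8)), np.zeros((2, 15, 16)))
        with pytest.raises(ValueError):
            model.fit(np.zeros((0, 8, 8)), np.zeros((0, 16, 16)))

    def test_sklearn_param_interface(self):
        model = SRGANSuperResolver(base_channels=8)
        params = model.get_params()
        assert params["base_channels"] == 8
        model.set_params(batch_size=2)
        assert model.batch_size == 2


class TestSuperResolve:
    def test_output_grid_spacing_and_clipping(self):
        rng = np.random.default_rng(10)
        lr_img = rng.uniform(-1, 1, size=(2, 16, 16))
        hr_img = rng.uniform(-1, 1, size=(2, 32, 32))
        model = SRGANSuperResolver(
            base_channels=4, n_residual_blocks=1, batch_size=2, epochs=1,
            max_iterations=2, rng_seed=1,
            disc_channel_plan=(4, 4, 4, 4, 8, 8, 8, 8),
            feat_channel_plan=(2, 2, 4, 4))
        model.fit(lr_img, hr_img)
        spec = acq.normalization_spec("T1")
        fast = ph.QuantMap(np.full((16, 16), 1200.0), "T1", pixel_spacing=2.0)
        out = super_resolve(model, fast, spec)
        assert out.grid == (32, 32)
        assert out.pixel_spacing == pytest.approx(1.0)
        assert out.values.min() >= 0
        assert out.values.max() <= out.physical_max

    def test_checkpoint_round_trip_preserves_outputs(self, tmp_path):
        from qmapsr.srgan import load_checkpoint, save_checkpoint
        rng = np.random.default_rng(12)
        lr_img = rng.uniform(-1, 1, size=(2, 8, 8))
        hr_img = rng.uniform(-1, 1, size=(2, 16, 16))
        model = SRGANSuperResolver(
            base_channels=4, n_residual_blocks=1, batch_size=2, epochs=5,
            max_iterations=5, rng_seed=2,
            disc_channel_plan=(4, 4, 4, 4, 8, 8, 8, 8),
            feat_channel_plan=(2, 2, 4, 4))
        model.fit(lr_img, hr_img)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        x = rng.uniform(-1, 1, size=(8, 8))
        assert np.allclose(loaded.transform(x), model.transform(x))
        assert loaded.get_params()["base_channels"] == 4

    def test_feature_extractor_is_fixed_and_seeded(self):
        feat_a = build_feature_extractor(TOY)
        feat_b = build_feature_extractor(TOY)
        x = np.random.default_rng(11).uniform(0, 1, size=(1, 1, 16, 16))
        assert np.array_equal(feat_a.forward(x, train=False),
                              feat_b.forward(x, train=False))
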