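"""GAN losses, SSIM term, networks and the training loop."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from polsynth import gan, nn
from polsynth.errors import ConfigurationError
from polsynth.ssim import gaussian_window, ssim_map, ssim_term


def brute_force_ssim(x, y, data_range=255.0, win=11, sigma=1.5):
    """Double-loop sliding-window SSIM reference."""
    k = gaussian_window(win, sigma)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = x.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            xw = x[i:i + win, j:j + win].astype(float)
            yw = y[i:i + win, j:j + win].astype(float)
            mx = (k * xw).sum()
            my = (k * yw).sum()
            sxx = (k * xw * xw).sum() - mx * mx
            syy = (k * yw * yw).sum() - my * my
            sxy = (k * xw * yw).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * sxy + c2))
                        / ((mx**2 + my**2 + c1) * (sxx + syy + c2)))
    return float(np.mean(vals))


class TestSsimTerm:
    def test_identity(self, rng):
        x = rng.uniform(0, 255, (20, 20))
        assert ssim_term(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 255, (16, 16))
            y = rng.uniform(0, 255, (16, 16))
            assert ssim_term(x, y) == pytest.approx(ssim_term(y, x), abs=1e-12)

    def test_constant_offset_luminance_only(self):
        mu1, mu2 = 40.0, 200.0
        x = np.full((16, 16), mu1)
        y = np.full((16, 16), mu2)
        c1 = (0.01 * 255) ** 2
        expected = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
        assert ssim_term(x, y) == pytest.approx(expected, abs=1e-12)
        assert ssim_term(x, y) < 1.0

    def test_matches_double_loop_oracle(self, rng):
        x = rng.uniform(0, 255, (16, 16))
        y = np.clip(x + rng.normal(0, 30, (16, 16)), 0, 255)
        assert ssim_term(x, y) == pytest.approx(brute_force_ssim(x, y),
                                                abs=1e-8)

    def test_matches_skimage(self, rng):
        x = rng.uniform(0, 255, (32, 32))
        y = np.clip(x + rng.normal(0, 20, (32, 32)), 0, 255)
        sk = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                   use_sample_covariance=False,
                                   data_range=255, win_size=11)
        assert ssim_term(x, y) == pytest.approx(sk, abs=1e-10)

    def test_tensor_path_matches_numpy_path(self, rng):
        x = rng.uniform(0, 255, (16, 16))
        y = rng.uniform(0, 255, (16, 16))
        t = ssim_term(nn.Tensor(x), nn.Tensor(y)).item()
        assert t == pytest.approx(ssim_term(x, y), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_term(np.zeros((12, 12)), np.zeros((13, 13)))


class TestGeneratorLoss:
    def test_perfect_prediction_zero_total(self, rng):
        x = rng.uniform(0, 255, (16, 16))
        total, comps = gan.generator_loss(None, x, x, gan.LossWeights())
        assert total == pytest.approx(0.0, abs=1e-9)
        assert comps["l1"] == 0.0

    def test_ssim_weight_zero_recovers_pix2pix_objective(self, rng):
        x = rng.uniform(0, 255, (16, 16))
        y = rng.uniform(0, 255, (16, 16))
        scores = rng.normal(size=(1, 1, 3, 3))
        w0 = gan.LossWeights(lambda_ssim=0.0)
        total, comps = gan.generator_loss(scores, x, y, w0)
        # bit-for-bit equality with the manually composed adv + L1 form
        adv = gan.nn.bce_with_logits(nn.Tensor(scores), 1.0).item()
        expected = w0.lambda_adv * adv + w0.lambda_l1 * np.mean(np.abs(x - y))
        assert total == expected
        assert comps["ssim"] is None

    def test_printed_2x2_hand_arithmetic(self):
        pred = np.zeros((2, 2))
        target = np.full((2, 2), 255.0)
        weights = gan.LossWeights(lambda_adv=0.0, lambda_l1=1.0,
                                  lambda_ssim=1.0)
        total, comps = gan.generator_loss(None, pred, target, weights)
        assert comps["l1"] == 255.0
        # 1x1 effective window -> luminance-only SSIM between constants
        c1 = (0.01 * 255) ** 2
        ssim = (2 * 0 * 255 + c1) / (0**2 + 255**2 + c1)
        assert total == pytest.approx(255.0 + (1 - ssim), abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            gan.generator_loss(None, np.zeros((4, 4)), np.zeros((4, 4)),
                               gan.LossWeights(lambda_l1=-1.0))


class TestDiscriminatorLoss:
    def test_perfect_discrimination_limit(self):
        big = np.full((1, 1, 3, 3), 50.0)
        assert gan.discriminator_loss(big, -big) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_zero_logits_give_ln2(self):
        z = np.zeros((1, 1, 4, 4))
        assert gan.discriminator_loss(z, z) == pytest.approx(np.log(2),
                                                             abs=1e-12)

    def test_matches_elementwise_bce_formula(self, rng):
        real = rng.normal(size=(1, 1, 5, 5))
        fake = rng.normal(size=(1, 1, 5, 5))

        def bce(x, t):
            p = 1 / (1 + np.exp(-x))
            return -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()

        expected = 0.5 * (bce(real, 1.0) + bce(fake, 0.0))
        assert gan.discriminator_loss(real, fake) == pytest.approx(expected,
                                                                   abs=1e-12)


SMALL_G = gan.GeneratorSpec(depth=2, base_channels=4)
SMALL_D = gan.DiscriminatorSpec(base_channels=4)


def tiny_pairs(rng, n, side=16):
    out = []
    for _ in range(n):
        x = rng.uniform(30, 255, (side, side))
        out.append((x, np.clip(255 - x, 0, 255)))
    return out


class TestTraining:
    def test_one_epoch_two_tiles_records_two_steps(self, rng):
        pairs = tiny_pairs(rng, 2)
        cfg = gan.TrainConfig(epochs=1, seed=0)
        bundle = gan.train_gan(pairs, pairs[:1], SMALL_G, SMALL_D,
                               gan.LossWeights(), cfg)
        assert bundle.n_generator_steps == 2
        assert len(bundle.history) == 1
        assert "val_masked_ssim" in bundle.history[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigurationError):
            gan.train_gan([], [], SMALL_G, SMALL_D, gan.LossWeights(),
                          gan.TrainConfig(epochs=1))

    def test_batch_size_must_be_one(self):
        with pytest.raises(ConfigurationError):
            gan.TrainConfig(batch_size=2).validate()

    def test_seeded_reproducibility_epoch1_losses(self, rng):
        pairs = tiny_pairs(rng, 3)
        cfg = gan.TrainConfig(epochs=1, seed=5)
        h1 = gan.train_gan(pairs, None, SMALL_G, SMALL_D, gan.LossWeights(),
                           cfg).history[0]
        h2 = gan.train_gan(pairs, None, SMALL_G, SMALL_D, gan.LossWeights(),
                           cfg).history[0]
        assert h1 == h2

    def test_bundle_save_load_roundtrip(self, rng, tmp_path):
        pairs = tiny_pairs(rng, 2)
        cfg = gan.TrainConfig(epochs=1, seed=0)
        bundle = gan.train_gan(pairs, pairs[:1], SMALL_G, SMALL_D,
                               gan.LossWeights(), cfg)
        bundle.save(tmp_path / "m.npz")
        loaded = gan.GanBundle.load(tmp_path / "m.npz")
        x = pairs[0][0]
        np.testing.assert_allclose(gan.synthesize(bundle, x),
                                   gan.synthesize(loaded, x), atol=1e-6)


class TestSynthesize:
    @pytest.mark.parametrize("side", [202, 128, 64])
    def test_output_shape_contract(self, side):
        gen = gan.UNetGenerator(gan.GeneratorSpec(depth=3, base_channels=2),
                                np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(0, 255, (side, side))
        out = gan.synthesize(gen, x)
        assert out.shape == (side, side)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_inference_deterministic(self, rng):
        gen = gan.UNetGenerator(SMALL_G, np.random.default_rng(0))
        x = rng.uniform(0, 255, (16, 16))
        np.testing.assert_array_equal(gan.synthesize(gen, x),
                                      gan.synthesize(gen, x))

    def test_beats_global_mean_baseline_on_recovery_task(self):
        from polsynth import tasks
        pairs = tasks.make_recovery_pairs(n_tiles=40, seed=9)
        train, val = pairs[:32], pairs[32:]
        cfg = gan.TrainConfig(learning_rate=2e-4, epochs=10, seed=0)
        bundle = gan.train_gan(train, val,
                               gan.GeneratorSpec(depth=3, base_channels=8),
                               gan.DiscriminatorSpec(base_channels=8),
                               gan.LossWeights(), cfg)
        global_mean = np.mean([y for _, y in train])
        err_model, err_base = [], []
        for x, y in val:
            pred = gan.synthesize(bundle.generator, x)
            err_model.append(np.abs(pred - y).mean())
            err_base.append(np.abs(global_mean - y).mean())
        assert np.mean(err_model) < np.mean(err_base)

        # domain shift: the trained generator applied to tiles from a
        # phantom with shifted noise/attenuation parameters still emits
        # valid in-range contrast (graceful degradation, no blow-up)
        import dataclasses

        from polsynth import phantom, preprocess
        shifted_cfg = dataclasses.replace(
            tasks.small_phantom_config(seed=5),
            attenuation_coeff_range=(0.02, 0.05), speckle_looks=1,
            depol_noise_sigma_dopu=0.2, depol_noise_sigma_ret=0.5)
        rng2 = shifted_cfg.rng()
        frame = phantom.generate_frame(shifted_cfg, "normal", rng2)
        tile = preprocess.convert_to_8bit(
            preprocess.split_into_tiles(frame.intensity, 32)[0].image)
        out = gan.synthesize(bundle.generator, tile)
        assert np.isfinite(out).all()
        assert out.min() >= 0 and out.max() <= 255

    def test_discriminator_has_three_feature_layers(self):
        disc = gan.PatchDiscriminator(SMALL_D, np.random.default_rng(0))
        assert len(disc.convs) == 3
        with pytest.raises(ConfigurationError):
            gan.DiscriminatorSpec(n_conv_layers=4).validate()
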