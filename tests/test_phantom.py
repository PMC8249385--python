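"""Phantom simulator: physics oracles, bounds and determinism."""

import numpy as np
import pytest

from polsynth import phantom
from polsynth.errors import ConfigurationError


def make_config(**kw):
    defaults = dict(image_height=64, image_width=32, n_layers_range=(2, 4),
                    dopu_kernel=3)
    defaults.update(kw)
    return phantom.PhantomConfig(**defaults)


class TestLayerStack:
    def test_degenerate_interval_pins_birefringence(self, rng):
        cfg = make_config(birefringence_range_normal=(1e-3, 1e-3))
        stack = phantom.simulate_layer_stack(cfg, "normal", rng)
        assert all(layer.delta_n == 1e-3 for layer in stack.layers)
        assert sum(layer.thickness for layer in stack.layers) == 64

    def test_cancer_zero_interval_gives_zero_stack(self, rng):
        cfg = make_config(birefringence_range_cancer=(0.0, 0.0))
        stack = phantom.simulate_layer_stack(cfg, "cancer", rng)
        assert all(layer.delta_n == 0.0 for layer in stack.layers)
        assert isinstance(stack.lesions, list)

    def test_same_seed_same_stack(self):
        cfg = make_config()
        s1 = phantom.simulate_layer_stack(cfg, "cancer", np.random.default_rng(5))
        s2 = phantom.simulate_layer_stack(cfg, "cancer", np.random.default_rng(5))
        assert s1 == s2

    def test_degenerate_config_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            phantom.simulate_layer_stack(
                make_config(n_layers_range=(5, 3)), "normal", rng)
        with pytest.raises(ConfigurationError):
            phantom.simulate_layer_stack(
                make_config(image_height=3, n_layers_range=(2, 4)), "normal", rng)


class TestCumulativeRetardation:
    def test_zero_birefringence_gives_zero_map(self):
        cfg = make_config()
        stack = phantom.LayerStack(layers=[
            phantom.Layer(64, 0.0, 0.5, 0.01)])
        np.testing.assert_array_equal(
            phantom.cumulative_retardation(stack, cfg), 0.0)

    def test_fold_fixed_point_at_quarter_wave(self):
        # single layer sized so the round-trip retardation at the bottom
        # is exactly pi/2: delta = 2 * (2 pi / lam) * dn * H * dz = pi/2
        cfg = make_config(image_height=50, pixel_depth_um=5.0,
                          wavelength_um=1.3)
        dn = (np.pi / 2) * 1.3 / (2 * 2 * np.pi * 50 * 5.0)
        stack = phantom.LayerStack(layers=[phantom.Layer(50, dn, 0.5, 0.01)])
        ret = phantom.cumulative_retardation(stack, cfg)
        assert ret[-1, 0] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_three_layer_profile_matches_bruteforce_cumsum(self):
        cfg = make_config(image_height=150, pixel_depth_um=5.0,
                          wavelength_um=1.3)
        spec = [(50, 1e-3), (50, 0.0), (50, 2e-3)]
        stack = phantom.LayerStack(layers=[
            phantom.Layer(t, dn, 0.5, 0.01) for t, dn in spec])
        ret = phantom.cumulative_retardation(stack, cfg)

        # independent per-pixel brute force
        acc, expected = 0.0, []
        for t, dn in spec:
            for _ in range(t):
                acc += dn * 5.0
                expected.append(2 * (2 * np.pi / 1.3) * acc)
        expected = phantom.fold_retardation(np.array(expected))
        np.testing.assert_allclose(ret[:, 0], expected, atol=1e-10)

    def test_constant_within_zero_birefringence_layer(self):
        cfg = make_config(image_height=60)
        stack = phantom.LayerStack(layers=[
            phantom.Layer(20, 1e-3, 0.5, 0.01),
            phantom.Layer(20, 0.0, 0.5, 0.01),
            phantom.Layer(20, 1e-3, 0.5, 0.01)])
        ret = phantom.cumulative_retardation(stack, cfg)
        assert np.ptp(ret[20:40, 0]) == 0.0


class TestSpeckledIntensity:
    def test_many_looks_approach_noiseless_log_signal(self, rng):
        cfg = make_config(speckle_looks=10_000)
        stack = phantom.simulate_layer_stack(cfg, "normal", rng)
        noisy = phantom.render_speckled_intensity(stack, cfg, rng).astype(float)
        clean = phantom.expected_intensity(stack, cfg).astype(float)
        rel = np.abs(noisy - clean) / np.maximum(clean, 1.0)
        assert rel.max() < 0.02

    def test_zero_attenuation_uniform_layer_constant_profile(self, rng):
        cfg = make_config(speckle_looks=1_000_000)
        stack = phantom.LayerStack(layers=[phantom.Layer(64, 0.0, 0.5, 1e-12)])
        with pytest.raises(ConfigurationError):
            # attenuation must be strictly positive
            phantom.render_speckled_intensity(
                phantom.LayerStack(layers=[phantom.Layer(64, 0.0, 0.5, 0.0)]),
                cfg, rng)
        img = phantom.render_speckled_intensity(stack, cfg, rng)
        assert np.ptp(img.astype(int), axis=0).max() <= 40  # quantization+residual speckle

    def test_seeded_determinism(self):
        cfg = make_config()
        outs = []
        for _ in range(2):
            r = np.random.default_rng(11)
            stack = phantom.simulate_layer_stack(cfg, "cancer", r)
            outs.append(phantom.render_speckled_intensity(stack, cfg, r))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestStokesAndDopu:
    def test_zero_retardation_zero_noise_single_state(self, rng):
        cfg = make_config()
        ret = np.zeros((8, 8))
        f = phantom.stokes_from_retardation(ret, cfg, rng, sigma=0.0)
        np.testing.assert_array_equal(f.q_comp, 1.0)
        np.testing.assert_array_equal(f.u_comp, 0.0)
        np.testing.assert_array_equal(f.v_comp, 0.0)

    def test_noise_free_field_fully_polarized(self, rng):
        cfg = make_config()
        ret = np.linspace(0, np.pi / 2, 64).reshape(8, 8)
        f = phantom.stokes_from_retardation(ret, cfg, rng, sigma=0.0)
        dop = np.sqrt(f.q_comp**2 + f.u_comp**2 + f.v_comp**2) / f.i_comp
        np.testing.assert_allclose(dop, 1.0, atol=1e-12)

    def test_quarter_wave_matches_rotation_matrix_oracle(self, rng):
        cfg = make_config()
        ret = np.full((4, 4), np.pi / 4)
        f = phantom.stokes_from_retardation(ret, cfg, rng, sigma=0.0)
        # rotation of (1, 0, 0) about the V axis by 2 * pi/4 via an
        # explicit rotation matrix
        a = np.pi / 2
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0],
                        [0, 0, 1.0]])
        expected = rot @ np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(
            [f.q_comp[0, 0], f.u_comp[0, 0], f.v_comp[0, 0]], expected,
            atol=1e-12)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            phantom.stokes_from_retardation(np.zeros((4, 4)), make_config(),
                                            rng, sigma=-1.0)

    def test_uniform_polarized_field_dopu_one(self):
        ones = np.ones((6, 6))
        f = phantom.StokesField(ones, ones * 0.6, ones * 0.8, ones * 0.0)
        for kernel in (1, 3, 5):
            np.testing.assert_allclose(phantom.compute_dopu(f, kernel), 1.0,
                                       atol=1e-12)

    def test_even_kernel_rejected(self):
        ones = np.ones((6, 6))
        f = phantom.StokesField(ones, ones, ones * 0, ones * 0)
        with pytest.raises(ConfigurationError):
            phantom.compute_dopu(f, 4)

    def test_antipodal_populations_match_explicit_sum(self):
        # 3x3 field: 5 pixels at +Q, 4 at -Q; center window average is
        # the 9-term mean, DOPU at the center is its norm
        q = np.array([[1.0, -1.0, 1.0],
                      [-1.0, 1.0, -1.0],
                      [1.0, -1.0, 1.0]])
        f = phantom.StokesField(np.ones((3, 3)), q, np.zeros((3, 3)),
                                np.zeros((3, 3)))
        dopu = phantom.compute_dopu(f, 3)
        assert dopu[1, 1] == pytest.approx(abs(q.mean()), abs=1e-15)

    def test_dopu_matches_double_loop_oracle(self, rng):
        ones = np.ones((16, 16))
        q = rng.uniform(-0.5, 0.5, (16, 16))
        u = rng.uniform(-0.5, 0.5, (16, 16))
        v = rng.uniform(-0.5, 0.5, (16, 16))
        f = phantom.StokesField(ones, q, u, v)
        dopu = phantom.compute_dopu(f, 5)
        oracle = np.zeros((16, 16))
        for i in range(16):
            for j in range(16):
                qs = us = vs = cnt = 0.0
                for di in range(-2, 3):
                    for dj in range(-2, 3):
                        if 0 <= i + di < 16 and 0 <= j + dj < 16:
                            qs += q[i + di, j + dj]
                            us += u[i + di, j + dj]
                            vs += v[i + di, j + dj]
                            cnt += 1
                oracle[i, j] = np.sqrt((qs / cnt) ** 2 + (us / cnt) ** 2
                                       + (vs / cnt) ** 2)
        np.testing.assert_allclose(dopu, oracle, atol=1e-12)


class TestDataset:
    def test_round_robin_case_assignment(self, small_config):
        frames, manifest = phantom.generate_dataset(small_config, 4, 2)
        assert len(frames) == 8
        counts = manifest.groupby("case_id").size()
        assert (counts == 2).all()

    def test_frames_satisfy_invariants(self, small_config):
        frames, _ = phantom.generate_dataset(small_config, 3, 1)
        for fr in frames:
            fr.validate()

    def test_class_separability_in_mean_retardation(self, small_config):
        rng = small_config.rng()
        means = {"cancer": [], "normal": []}
        for label in means:
            for i in range(25):
                fr = phantom.generate_frame(small_config, label, rng)
                means[label].append(fr.retardation.mean())
        assert np.mean(means["normal"]) > np.mean(means["cancer"])

    def test_zero_frames_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            phantom.generate_dataset(small_config, 0, 1)

    def test_bounds_hold_over_random_configs(self):
        master = np.random.default_rng(99)
        for _ in range(100):
            cfg = phantom.PhantomConfig(
                image_height=int(master.integers(24, 48)),
                image_width=int(master.integers(24, 48)),
                n_layers_range=(1, 3),
                speckle_looks=int(master.integers(1, 8)),
                depol_noise_sigma_dopu=float(master.uniform(0.01, 0.3)),
                depol_noise_sigma_ret=float(master.uniform(0.35, 0.9)),
                dopu_kernel=int(master.choice([3, 5])),
                rng_seed=int(master.integers(2**31)),
            )
            label = "cancer" if master.integers(2) else "normal"
            fr = phantom.generate_frame(cfg, label, cfg.rng())
            fr.validate()  # asserts DOPU/retardation/intensity bounds

    def test_triplet_determinism_under_seed(self, small_config):
        f1 = phantom.generate_frame(small_config, "cancer", small_config.rng())
        f2 = phantom.generate_frame(small_config, "cancer", small_config.rng())
        np.testing.assert_array_equal(f1.intensity, f2.intensity)
        np.testing.assert_array_equal(f1.dopu, f2.dopu)
        np.testing.assert_array_equal(f1.retardation, f2.retardation)
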