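"""Layer-library gradient checks and model architecture contracts."""

import numpy as np
import pytest

import sdmfuse as sf
from sdmfuse import nn
from sdmfuse.model import ModelConfig


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def check_layer_gradients(layer, x, train=True, atol=1e-6):
    """Finite-difference check of input and parameter gradients through a
    scalar loss sum(y * w) with fixed random w."""
    rng = np.random.default_rng(0)
    y = layer.forward(x, train)
    w = rng.normal(size=y.shape)

    def loss():
        return float((layer.forward(x, train) * w).sum())

    layer.forward(x, train)
    dx = layer.backward(w.copy())
    assert np.allclose(dx, numeric_grad(loss, x), atol=atol)
    for p in layer.params():
        p.grad[...] = 0.0
        layer.forward(x, train)
        layer.backward(w.copy())
        assert np.allclose(p.grad, numeric_grad(loss, p.value), atol=atol)


class TestLayerGradients:
    rng = np.random.default_rng(42)

    def test_linear(self):
        check_layer_gradients(nn.Linear(4, 3, self.rng),
                              self.rng.normal(size=(5, 4)))

    def test_conv2d_stride1_padded(self):
        check_layer_gradients(nn.Conv2d(2, 3, 3, 1, 1, self.rng),
                              self.rng.normal(size=(2, 2, 5, 5)))

    def test_conv2d_stride2(self):
        check_layer_gradients(nn.Conv2d(2, 2, 3, 2, 1, self.rng),
                              self.rng.normal(size=(2, 2, 6, 6)))

    def test_batchnorm_2d_and_4d(self):
        check_layer_gradients(nn.BatchNorm(3),
                              self.rng.normal(size=(6, 3)), atol=1e-5)
        check_layer_gradients(nn.BatchNorm(2),
                              self.rng.normal(size=(3, 2, 4, 4)), atol=1e-5)

    def test_residual_block(self):
        block = nn.ResidualBlock(2, 3, 2, self.rng)
        # move off the zero-init so the second BN path has gradients
        for p in block.params():
            p.value += self.rng.normal(0, 0.05, size=p.value.shape)
        check_layer_gradients(block, self.rng.normal(size=(3, 2, 6, 6)),
                              atol=1e-5)

    def test_global_avg_pool(self):
        check_layer_gradients(nn.GlobalAvgPool(),
                              self.rng.normal(size=(2, 3, 4, 4)))


class TestLayerSemantics:
    def test_dropout_eval_is_identity_and_train_scales(self):
        rng = np.random.default_rng(0)
        layer = nn.Dropout(0.5, rng)
        x = np.ones((200, 50))
        assert np.array_equal(layer.forward(x, train=False), x)
        y = layer.forward(x, train=True)
        assert set(np.unique(y)) == {0.0, 2.0}
        assert abs(y.mean() - 1.0) < 0.05  # inverted scaling keeps the mean

    def test_residual_block_is_identity_plus_shortcut_at_init(self):
        rng = np.random.default_rng(1)
        block = nn.ResidualBlock(3, 3, 1, rng)
        x = np.abs(rng.normal(size=(4, 3, 8, 8)))
        # zero-initialized second batch norm silences the residual branch:
        # with an identity shortcut the output is ReLU(x) = x for x > 0
        np.testing.assert_allclose(block.forward(x, train=False), x)

    def test_adam_decreases_quadratic(self):
        p = nn.Param(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad[...] = 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-2


def tiny_config(**kw):
    defaults = dict(n_species=6, n_genera=3, n_families=2, climate_dim=5,
                    mlp_hidden=(8, 8, 12, 12), mlp_dropout=0.25,
                    encoder_width=4, encoder_depth=2, fusion_dim=10, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestArchitectures:
    def test_climate_mlp_shapes_and_eval_determinism(self):
        net = sf.build_climate_mlp(tiny_config())
        x = np.random.default_rng(0).normal(size=(2, 5))
        out = net.forward(None, x)
        assert out.species_logits.shape == (2, 6)
        assert out.genus_logits.shape == (2, 3)
        assert out.family_logits.shape == (2, 2)
        again = net.forward(None, x)
        np.testing.assert_array_equal(out.species_logits, again.species_logits)

    def test_species_head_width_matches_species_count(self):
        net = sf.build_climate_mlp(tiny_config(n_species=17))
        assert net.heads.species.W.value.shape == (12, 17)

    def test_encoder_rejects_wrong_channels_and_small_patches(self):
        net = sf.build_image_encoder(tiny_config())
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="expected images"):
            net.forward(rng.normal(size=(1, 3, 16, 16)), None)
        with pytest.raises(ValueError, match=">= 4 px"):
            net.forward(rng.normal(size=(1, 4, 2, 2)), None)

    def test_encoder_finite_logits(self):
        net = sf.build_image_encoder(tiny_config())
        x = np.random.default_rng(1).uniform(size=(3, 4, 16, 16))
        out = net.forward(x, None)
        assert np.all(np.isfinite(out.species_logits))
        assert out.species_logits.shape == (3, 6)

    def test_fused_same_seed_identical_parameters(self):
        a = sf.build_fused_model(tiny_config(seed=11))
        b = sf.build_fused_model(tiny_config(seed=11))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_fused_zeroed_climate_branch_is_image_only_function(self):
        net = sf.build_fused_model(tiny_config())
        split = net.config.encoder_feature_dim
        net.fusion.W.value[split:, :] = 0.0  # silence the climate inputs
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(2, 4, 16, 16))
        out1 = net.forward(img, rng.normal(size=(2, 5)))
        out2 = net.forward(img, rng.normal(size=(2, 5)))
        np.testing.assert_allclose(out1.species_logits, out2.species_logits)

    def test_species_relabeling_equivariance(self):
        cfg = tiny_config()
        net = sf.build_climate_mlp(cfg)
        x = np.random.default_rng(3).normal(size=(4, 5))
        base = net.forward(None, x).species_logits
        perm = np.random.default_rng(4).permutation(cfg.n_species)
        net.heads.species.W.value = net.heads.species.W.value[:, perm]
        net.heads.species.b.value = net.heads.species.b.value[perm]
        np.testing.assert_allclose(net.forward(None, x).species_logits,
                                   base[:, perm])

    def test_predict_probabilities_sigmoid_contract(self):
        net = sf.build_climate_mlp(tiny_config())
        x = np.random.default_rng(5).normal(size=(3, 5))
        probs = sf.predict_probabilities(net, (None, x))
        logits = net.forward(None, x).species_logits
        assert np.all((probs > 0) & (probs < 1))
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(-logits)))
        # multilabel: rows need not sum to 1
        assert not np.allclose(probs.sum(axis=1), 1.0)

    def test_checkpoint_round_trip(self, tmp_path):
        net = sf.build_fused_model(tiny_config(seed=8))
        x_img = np.random.default_rng(6).uniform(size=(2, 4, 16, 16))
        x_clim = np.random.default_rng(7).normal(size=(2, 5))
        before = net.forward(x_img, x_clim).species_logits
        sf.save_checkpoint(tmp_path / "m.npz", net)
        back, _, _ = sf.load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            back.forward(x_img, x_clim).species_logits, before)
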