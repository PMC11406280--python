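"""Loss functions, completeness estimation, and the training loop."""

import math

import numpy as np
import pytest

import sdmfuse as sf
from sdmfuse.model import ModelConfig
from sdmfuse.training import single_label_ce


def logit(p):
    return math.log(p / (1 - p))


class TestSamplingAwareBCE:
    def test_hand_value_two_species(self):
        # P = {s1}, A = {s2}, both p = 0.5, c = 1 -> L = 2 ln 2
        logits = np.array([[0.0, 0.0]])
        targets = np.array([[1, 0]])
        value = sf.sampling_aware_bce(logits, targets, np.array([1.0]))
        assert value == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_zero_completeness_kills_absent_gradients(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 6))
        targets = np.zeros((3, 6), dtype=int)
        targets[:, :2] = 1
        _, grad = sf.sampling_aware_bce(logits, targets, np.zeros(3),
                                        return_grad=True)
        assert np.all(grad[:, 2:] == 0.0)
        assert np.all(grad[:, :2] != 0.0)

    def test_balanced_row_matches_plain_bce_up_to_normalization(self):
        # |P| = |A| = 3 and c = 1: both terms average over 3 entries, so the
        # loss equals mean BCE times (S / |P|) = 2
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(4, 6))
        targets = np.tile([1, 1, 1, 0, 0, 0], (4, 1))
        sa = sf.sampling_aware_bce(logits, targets, np.ones(4))
        bce = sf.multilabel_bce(logits, targets)
        assert sa == pytest.approx(2 * bce, abs=1e-9)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n, s = rng.integers(1, 5), rng.integers(2, 7)
            targets = np.zeros((n, s), dtype=int)
            for i in range(n):
                targets[i, rng.choice(s, rng.integers(1, s), replace=False)] = 1
            logits = rng.normal(size=(n, s))
            c = rng.uniform(0.1, 1.0, size=n)
            _, grad = sf.sampling_aware_bce(logits, targets, c,
                                            return_grad=True)
            eps = 1e-6
            num = np.zeros_like(logits)
            for idx in np.ndindex(*logits.shape):
                z = logits.copy()
                z[idx] += eps
                hi = sf.sampling_aware_bce(z, targets, c)
                z[idx] -= 2 * eps
                lo = sf.sampling_aware_bce(z, targets, c)
                num[idx] = (hi - lo) / (2 * eps)
            assert np.allclose(grad, num, atol=1e-4)

    def test_monotone_in_probabilities(self):
        # decreasing in p for present species, increasing for absent (c > 0)
        targets = np.array([[1, 0]])
        c = np.array([0.7])
        for z_lo, z_hi in [(-1.0, 0.5), (0.0, 2.0)]:
            lo = sf.sampling_aware_bce(np.array([[z_lo, 0.0]]), targets, c)
            hi = sf.sampling_aware_bce(np.array([[z_hi, 0.0]]), targets, c)
            assert hi < lo  # higher presence logit -> lower loss
            lo = sf.sampling_aware_bce(np.array([[0.0, z_lo]]), targets, c)
            hi = sf.sampling_aware_bce(np.array([[0.0, z_hi]]), targets, c)
            assert hi > lo  # higher absence logit -> higher loss

    def test_row_without_positives_rejected(self):
        with pytest.raises(ValueError, match="present species"):
            sf.sampling_aware_bce(np.zeros((1, 2)), np.zeros((1, 2)),
                                  np.ones(1))

    def test_all_present_row_has_no_absent_term(self):
        value = sf.sampling_aware_bce(np.zeros((1, 3)), np.ones((1, 3)),
                                      np.ones(1))
        assert value == pytest.approx(math.log(2))


class TestMultilabelBCE:
    def test_half_probabilities_give_ln2(self):
        assert sf.multilabel_bce(np.zeros((3, 4)), np.ones((3, 4))) \
            == pytest.approx(math.log(2))

    def test_confident_correct_limits_to_zero(self):
        logits = np.array([[40.0, -40.0]])
        targets = np.array([[1, 0]])
        assert sf.multilabel_bce(logits, targets) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_is_sigmoid_minus_target_scaled(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(2, 3))
        targets = np.array([[1, 0, 1], [0, 1, 0]])
        _, grad = sf.multilabel_bce(logits, targets, return_grad=True)
        expected = (1 / (1 + np.exp(-logits)) - targets) / logits.size
        np.testing.assert_allclose(grad, expected)


class TestMultirankLoss:
    def _outputs(self, rng):
        return sf.ModelOutputs(rng.normal(size=(2, 4)), rng.normal(size=(2, 2)),
                               rng.normal(size=(2, 1)))

    def test_species_only_weighting(self):
        rng = np.random.default_rng(4)
        outputs = self._outputs(rng)
        targets = (np.array([[1, 0, 1, 0], [0, 1, 0, 0]]),
                   np.array([[1, 0], [0, 1]]), np.array([[1], [1]]))
        c = np.array([1.0, 0.5])
        total, grads = sf.multirank_loss(outputs, targets, c, (1.0, 0.0, 0.0))
        species_only = sf.sampling_aware_bce(outputs.species_logits,
                                             targets[0], c)
        assert total == pytest.approx(species_only)
        assert np.all(grads[1] == 0) and np.all(grads[2] == 0)

    def test_equal_weights_sum_three_rank_terms(self):
        rng = np.random.default_rng(5)
        outputs = self._outputs(rng)
        targets = (np.array([[1, 1, 0, 0], [1, 0, 0, 0]]),
                   np.array([[1, 0], [1, 0]]), np.array([[1], [1]]))
        c = np.ones(2)
        total, _ = sf.multirank_loss(outputs, targets, c, (1.0, 1.0, 1.0))
        parts = [sf.sampling_aware_bce(z, t, c) for z, t in
                 zip((outputs.species_logits, outputs.genus_logits,
                      outputs.family_logits), targets)]
        assert total == pytest.approx(sum(parts))


class TestSingleLabelCE:
    def test_uniform_logits_give_log_s(self):
        rng = np.random.default_rng(0)
        value = single_label_ce(np.zeros((2, 5)), np.eye(5)[[0, 3]], rng)
        assert value == pytest.approx(math.log(5))


class TestCompleteness:
    def _labels(self, points, species):
        return [sf.LabelSet(f"a{i}", float(x), float(y), s,
                            frozenset({s}))
                for i, ((x, y), s) in enumerate(zip(points, species))]

    def test_richness_ratio_with_cap(self):
        # cluster A: 4 species within 256 m; cluster B: 2 species; with the
        # reference at quantile 1.0, n_ref = 4 -> B anchors get 0.5
        pts = [(0, 0), (50, 0), (0, 50), (50, 50),
               (5000, 0), (5050, 0)]
        labels = self._labels(pts, [0, 1, 2, 3, 4, 5])
        c = sf.estimate_location_completeness(labels, radius_m=256,
                                              reference_quantile=1.0)
        assert all(c[f"a{i}"] == 1.0 for i in range(4))
        assert c["a4"] == pytest.approx(0.5)
        assert c["a5"] == pytest.approx(0.5)

    def test_uniform_richness_all_ones(self):
        pts = [(0, 0), (5000, 0), (10_000, 0)]
        labels = self._labels(pts, [0, 1, 2])
        c = sf.estimate_location_completeness(labels)
        assert set(c.values()) == {1.0}


class TestLearningRateSweep:
    def test_half_decade_steps_cover_stated_range(self):
        rates = sf.learning_rate_sweep()
        assert rates[0] == pytest.approx(5e-6)
        assert rates[-1] <= 1e-1
        ratios = np.diff(np.log10(rates))
        assert np.allclose(ratios, 0.5)


class TestTrainModel:
    def _setup(self, n=96, s=6, seed=0):
        rng = np.random.default_rng(seed)
        climate = rng.normal(size=(n, 4))
        w = rng.normal(size=(4, s)) * 2
        present = (climate @ w + rng.normal(size=(n, s)) * 0.3) > 0
        present[:, 0] = True  # every row needs >= 1 positive
        samples = []
        for i in range(n):
            sp = frozenset(np.flatnonzero(present[i]).tolist())
            ls = sf.LabelSet(f"a{i:03d}", float(i), 0.0, min(sp), sp,
                             frozenset({j // 2 for j in sp}),
                             frozenset({j // 3 for j in sp}))
            samples.append(sf.SampleRecord(
                f"a{i:03d}", float(i), 0.0,
                np.zeros((4, 4, 4), dtype=np.float32), climate[i], 1.0, ls))
        split = sf.SplitSpec(frozenset(f"a{i:03d}" for i in range(72)),
                             frozenset(f"a{i:03d}" for i in range(72, n)),
                             0.0, "uniform")
        config = ModelConfig(n_species=s, n_genera=3, n_families=2,
                             climate_dim=4, mlp_hidden=(16, 16, 24, 24),
                             encoder_width=4, encoder_depth=2, seed=seed)
        return samples, split, config

    def test_loss_decreases_on_learnable_signal(self):
        samples, split, config = self._setup()
        net = sf.build_climate_mlp(config)
        net, hist = sf.train_model(net, samples, split,
                                   sf.TrainConfig(epochs=5, learning_rate=3e-3,
                                                  batch_size=24, seed=0))
        assert hist.epoch_loss[-1] < hist.epoch_loss[0]
        assert hist.selected_epoch == int(np.argmax(hist.epoch_auc))

    def test_zero_learning_rate_keeps_weights_and_flat_history(self):
        import dataclasses
        samples, split, config = self._setup()
        # dropout off so the forward pass is deterministic and the per-epoch
        # mean loss is exactly the dataset mean regardless of batch order
        config = dataclasses.replace(config, mlp_dropout=0.0)
        net = sf.build_climate_mlp(config)
        before = [p.value.copy() for p in net.params()]
        net, hist = sf.train_model(net, samples, split,
                                   sf.TrainConfig(epochs=3, learning_rate=0.0,
                                                  batch_size=24, seed=0))
        for p, b in zip(net.params(), before):
            np.testing.assert_array_equal(p.value, b)
        assert np.ptp(hist.epoch_loss) < 1e-9

    def test_same_seed_identical_history(self):
        samples, split, config = self._setup()
        runs = []
        for _ in range(2):
            net = sf.build_climate_mlp(config)
            _, hist = sf.train_model(net, samples, split,
                                     sf.TrainConfig(epochs=3,
                                                    learning_rate=2e-3,
                                                    batch_size=24, seed=5))
            runs.append((hist.epoch_loss, hist.epoch_auc))
        assert runs[0] == runs[1]
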