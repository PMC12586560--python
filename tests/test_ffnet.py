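"""FF core: goodness, probabilities, normalization, schedule, locality, training."""

import copy
import math

import numpy as np
import pytest
from scipy.special import expit

import ffcnn as F
from ffcnn.errors import ConfigurationError, ConsistencyError
from ffcnn.ffnet import Adam, ff_train_step


class TestGoodness:
    def test_zero_and_hand_sum(self):
        assert F.goodness(np.zeros((1, 5)))[0] == 0.0
        assert F.goodness(np.array([[1.0, 2.0]]))[0] == 5.0

    def test_equals_squared_norm(self, rng):
        x = rng.normal(size=(3, 4, 5, 6))
        np.testing.assert_allclose(
            F.goodness(x), [np.linalg.norm(xi) ** 2 for xi in x], rtol=1e-12
        )


class TestLayerProbability:
    def test_symmetry_point(self):
        assert F.layer_probability(7.0, 7.0, "positive") == pytest.approx(0.5)
        assert F.layer_probability(7.0, 7.0, "negative") == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        assert F.layer_probability(10.0, 7.0, "positive") == pytest.approx(
            1 / (1 + math.exp(-3)), abs=1e-10
        )

    def test_polarities_sum_to_one(self, rng):
        g = rng.uniform(0, 100, size=20)
        p = F.layer_probability(g, 40.0, "positive")
        n = F.layer_probability(g, 40.0, "negative")
        np.testing.assert_allclose(p + n, 1.0, atol=1e-12)


class TestCombinedLoss:
    def test_half_probability_gives_ln2(self):
        assert F.combined_loss([np.array([0.5])]) == pytest.approx(math.log(2))

    def test_perfect_probability_gives_zero(self):
        assert F.combined_loss([np.array([1.0])]) == pytest.approx(0.0, abs=1e-12)

    def test_two_layers_sum_of_negative_logs(self):
        p1, p2 = 0.7, 0.9
        expected = -math.log(p1) - math.log(p2)
        assert F.combined_loss([np.array([p1]), np.array([p2])]) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigurationError):
            F.combined_loss([])


class TestLayerNormalize:
    def test_hand_evaluation(self):
        out = F.layer_normalize(np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(out, [[3 / math.sqrt(12.5), 4 / math.sqrt(12.5)]],
                                   rtol=1e-6)

    def test_unit_rms(self, rng):
        x = rng.normal(size=(4, 3, 5, 5)) * 10
        out = F.layer_normalize(x)
        rms = np.sqrt((out.reshape(4, -1) ** 2).mean(axis=1))
        np.testing.assert_allclose(rms, 1.0, atol=1e-6)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 1, size=(2, 8))
        np.testing.assert_allclose(F.layer_normalize(x), F.layer_normalize(10 * x),
                                   rtol=1e-6)

    def test_all_zero_guarded(self):
        out = F.layer_normalize(np.zeros((1, 4)))
        assert np.all(np.isfinite(out)) and np.all(out == 0)


class TestLrSchedule:
    @pytest.mark.parametrize(
        "e,E,lr,expected",
        [
            (1, 100, 1e-3, 1e-3),
            (50, 100, 1e-3, 1e-3),
            (51, 100, 1e-3, 1e-3),       # continuous at the halfway point
            (100, 100, 1e-3, 2e-5),
            (75, 100, 2e-4, (2 * 2e-4 / 100) * 26),
        ],
    )
    def test_values(self, e, E, lr, expected):
        assert F.lr_schedule(e, E, lr) == pytest.approx(expected, rel=1e-12)

    def test_epoch_bounds(self):
        with pytest.raises(ValueError):
            F.lr_schedule(0, 10, 1e-3)


def _toy_net(seed=0, n_layers=2, norm="layer_norm"):
    return F.FFNetwork((1, 6, 6), n_layers=n_layers, filters=2, kernel=3,
                       norm=norm, n_classes=2, seed=seed)


def _layer_loss(net, x, li, polarity):
    """Oracle: recompute layer li's BCE loss from a fresh forward pass."""
    caches = net.forward(x)
    theta = net.layers[li].theta(6, 6)
    p = F.layer_probability(caches[li].g, theta, polarity)
    return F.combined_loss([p])


class TestForward:
    def test_single_layer_goodness_composition(self, rng):
        net = _toy_net(n_layers=1)
        x = rng.uniform(size=(3, 1, 6, 6))
        caches = net.forward(x)
        assert caches[0].g == pytest.approx(F.goodness(caches[0].y))

    def test_zero_weights_give_zero_goodness(self, rng):
        net = _toy_net()
        for layer in net.layers:
            layer.W[:] = 0
        caches = net.forward(rng.uniform(size=(2, 1, 6, 6)))
        assert all(np.all(c.g == 0) for c in caches)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ConsistencyError):
            _toy_net().forward(rng.uniform(size=(2, 1, 5, 5)))

    def test_theta_matches_activation_count(self, rng):
        net = _toy_net()
        caches = net.forward(rng.uniform(size=(2, 1, 6, 6)))
        for layer, cache in zip(net.layers, caches):
            n_activations = int(np.prod(cache.y.shape[1:]))
            assert layer.theta(6, 6) == n_activations

    def test_downstream_input_invariant_to_activation_scale(self, rng):
        # multiplying a layer's output by any positive constant leaves the
        # next layer's input unchanged (homogeneity of RMS normalization)
        net = _toy_net()
        x = rng.uniform(size=(2, 1, 6, 6))
        cache = net.layers[0].forward(x)
        out1 = net.layers[0].output_for_next(cache)
        scaled = copy.deepcopy(cache)
        scaled.y = cache.y * 7.3
        out2 = net.layers[0].output_for_next(scaled)
        np.testing.assert_allclose(out1, out2, rtol=1e-6)


class TestLocality:
    """The defining FF property: no gradient crosses a layer boundary."""

    def test_implementation_gradient_matches_fd_of_local_loss(self, rng):
        net = _toy_net(seed=3)
        x_pos = rng.uniform(size=(2, 1, 6, 6))
        x_neg = rng.uniform(size=(2, 1, 6, 6))
        opts = [Adam(l.parameters()) for l in net.layers]
        stats = ff_train_step(net, opts, x_pos, x_neg, lr=1e-3, apply_update=False)
        for li in range(2):
            W = net.layers[li].W
            got = stats["gradients"][li]["W"]
            h = 1e-6
            for idx in [(0, 0, 0, 0), (1, 0, 2, 1), (0, 0, 1, 2)]:
                orig = W[idx]
                W[idx] = orig + h
                up = _layer_loss(net, x_pos, li, "positive") + _layer_loss(
                    net, x_neg, li, "negative")
                W[idx] = orig - h
                dn = _layer_loss(net, x_pos, li, "positive") + _layer_loss(
                    net, x_neg, li, "negative")
                W[idx] = orig
                fd = (up - dn) / (2 * h)
                assert got[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_later_layer_loss_contributes_zero_gradient_to_earlier_weights(self, rng):
        # the gradient applied to layer 1 is identical whether or not layer 2's
        # loss is part of the combined objective: cross-layer terms are zero
        net = _toy_net(seed=4)
        x_pos = rng.uniform(size=(2, 1, 6, 6))
        x_neg = rng.uniform(size=(2, 1, 6, 6))
        opts = [Adam(l.parameters()) for l in net.layers]
        both = ff_train_step(net, opts, x_pos, x_neg, lr=1e-3,
                             apply_update=False)["gradients"][0]["W"]
        only_first = ff_train_step(net, opts, x_pos, x_neg, lr=1e-3,
                                   layer_subset=[0], apply_update=False)
        only = only_first["gradients"][0]["W"]
        assert np.max(np.abs(both - only)) < 1e-8

    def test_combined_step_equals_per_layer_steps(self, rng):
        x_pos = rng.uniform(size=(3, 1, 6, 6))
        x_neg = rng.uniform(size=(3, 1, 6, 6))
        net_a = _toy_net(seed=5)
        net_b = _toy_net(seed=5)
        opts_a = [Adam(l.parameters()) for l in net_a.layers]
        opts_b = [Adam(l.parameters()) for l in net_b.layers]
        ff_train_step(net_a, opts_a, x_pos, x_neg, lr=1e-3)
        for li in range(2):
            ff_train_step(net_b, opts_b, x_pos, x_neg, lr=1e-3, layer_subset=[li])
        for la, lb in zip(net_a.layers, net_b.layers):
            np.testing.assert_allclose(la.W, lb.W, atol=1e-10)
            np.testing.assert_allclose(la.b, lb.b, atol=1e-10)


class TestBatchNormVariant:
    def test_affine_gradients_match_finite_differences(self, rng):
        net = _toy_net(seed=6, norm="batch_norm")
        x_pos = rng.uniform(size=(4, 1, 6, 6))
        x_neg = rng.uniform(size=(4, 1, 6, 6))
        opts = [Adam(l.parameters()) for l in net.layers]
        # second layer: its BN input is layer 1's detached output
        stats = ff_train_step(net, opts, x_pos, x_neg, lr=1e-3, apply_update=False)
        li = 1
        layer = net.layers[li]

        def loss():
            c_p = net.forward(x_pos, training=True)
            c_n = net.forward(x_neg, training=True)
            theta = layer.theta(6, 6)
            return F.combined_loss(
                [F.layer_probability(c_p[li].g, theta, "positive")]
            ) + F.combined_loss([F.layer_probability(c_n[li].g, theta, "negative")])

        h = 1e-6
        for pname in ("gamma", "beta"):
            param = getattr(layer, pname)
            got = stats["gradients"][li][pname]
            orig = param[0]
            param[0] = orig + h
            up = loss()
            param[0] = orig - h
            dn = loss()
            param[0] = orig
            fd = (up - dn) / (2 * h)
            assert got[0] == pytest.approx(fd, rel=1e-3, abs=1e-6)

    def test_running_stats_update_only_in_training(self, rng):
        net = _toy_net(seed=7, norm="batch_norm")
        x = rng.uniform(size=(4, 1, 6, 6))
        before = net.layers[0].running_mean.copy()
        net.forward(x, training=False)
        np.testing.assert_array_equal(net.layers[0].running_mean, before)
        net.forward(x, training=True)
        assert not np.array_equal(net.layers[0].running_mean, before)


class TestTraining:
    def test_loss_decreases_early(self, tiny_net):
        _, history = tiny_net
        diffs = np.diff(history.combined_loss[:5])
        assert (diffs >= 0).sum() <= 1  # allow at most one non-decreasing step

    def test_history_shape_and_ranges(self, tiny_net):
        net, history = tiny_net
        assert len(history.epochs) == 8
        for li in range(net.n_layers):
            accs = history.layer_accuracy[li]
            assert len(accs) == 8 and all(0 <= a <= 1 for a in accs)

    def test_seeded_runs_are_bit_identical(self, shapes4, fourier4):
        train, _ = shapes4
        nets = []
        for _ in range(2):
            net = F.FFNetwork((1, 16, 16), n_layers=2, filters=3, kernel=3,
                              n_classes=4, seed=11)
            tc = F.TrainConfig(epochs=2, lr=1e-3, batch_size=25, K=0.35, seed=11,
                               track_accuracy=False)
            net, _h = F.train_ff(net, train, fourier4, tc)
            nets.append(net)
        for la, lb in zip(nets[0].layers, nets[1].layers):
            np.testing.assert_array_equal(la.W, lb.W)
            np.testing.assert_array_equal(la.b, lb.b)

    def test_first_layer_excluded_from_combined_loss(self, tiny_net):
        net, history = tiny_net
        assert net.loss_layer_indices() == [1, 2]
        expected = history.layer_loss[1][-1] + history.layer_loss[2][-1]
        assert history.combined_loss[-1] == pytest.approx(expected, rel=1e-9)


class TestCheckpoint:
    def test_round_trip(self, tiny_net, fourier4, tmp_path):
        net, _ = tiny_net
        tc = F.TrainConfig(epochs=8, lr=3e-3, batch_size=16, K=0.35, seed=1)
        F.save_checkpoint(tmp_path / "ck", net, fourier4, tc)
        net2, bank2, tc2, head2 = F.load_checkpoint(tmp_path / "ck")
        assert head2 is None and tc2.K == 0.35
        assert bank2.specs == fourier4.specs
        for la, lb in zip(net.layers, net2.layers):
            np.testing.assert_array_equal(la.W, lb.W)
        x = np.random.default_rng(0).uniform(size=(2, 1, 16, 16))
        np.testing.assert_allclose(net.forward(x)[2].g, net2.forward(x)[2].g)
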