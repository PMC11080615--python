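import numpy as np
import pytest

from perseclock import (
    ClockConfig, MLPClockRegressor, PerSEClockRegressor, build_model,
    forward, global_average_pool, load_checkpoint, reshape_to_blocks,
    save_checkpoint, scale,
)
from perseclock._network import (
    Adam, BatchNorm1d, Dropout, LeakyReLU, Linear, Network, SqueezeExcite,
    _sigmoid,
)
from perseclock.model import build_network, excitation


class TestReshape:
    def test_reference_geometry(self):
        """24,516 loci fill a 3 x 6 x 1,362 block tensor exactly."""
        cfg = ClockConfig()  # defaults: 3, 6, 1362
        x = np.arange(24516, dtype=float) / 24516
        t = reshape_to_blocks(x, cfg)
        assert t.shape == (3, 6, 1362)
        assert t.size == 24516

    def test_adjacent_loci_in_different_channels(self):
        cfg = ClockConfig(channels=5, se_reduction=5)
        x = np.arange(90, dtype=float)
        t = reshape_to_blocks(x, cfg)
        # element i -> channel i % 5, within-channel position i // 5 (row-major)
        for i in range(90):
            p = i // 5
            assert t[p // 6, p % 6, i % 5] == i

    def test_single_channel_identity(self):
        cfg = ClockConfig(channels=1, se_reduction=1)
        t = reshape_to_blocks(np.arange(18, dtype=float), cfg)
        assert list(t.reshape(-1)) == list(range(18))

    def test_round_trip(self, rng):
        cfg = ClockConfig(channels=5, se_reduction=5)
        x = rng.random(90)
        t = reshape_to_blocks(x, cfg)
        np.testing.assert_array_equal(t.reshape(-1), x)

    def test_wrong_length_reports_both_numbers(self):
        with pytest.raises(ValueError, match="100.*24516|24516.*100"):
            reshape_to_blocks(np.zeros(100), ClockConfig())


class TestGlobalAveragePool:
    def test_constant_channel(self):
        t = np.full((3, 6, 2), 0.5)
        np.testing.assert_allclose(global_average_pool(t), [0.5, 0.5])

    def test_reference_output_length(self, rng):
        t = rng.random((3, 6, 1362))
        assert global_average_pool(t).shape == (1362,)

    def test_matches_explicit_summation(self, rng):
        t = rng.random((3, 6, 4))
        pooled = global_average_pool(t)
        for c in range(4):
            total = sum(t[r, k, c] for r in range(3) for k in range(6))
            assert pooled[c] == pytest.approx(total / 18, abs=1e-12)


class TestScale:
    def test_identity_gates(self, rng):
        t = rng.random((3, 6, 4))
        np.testing.assert_array_equal(scale(t, np.ones(4)), t)

    def test_zero_gate_silences_one_channel(self, rng):
        t = rng.random((3, 6, 4))
        gates = np.array([1.0, 0.0, 1.0, 1.0])
        out = scale(t, gates)
        assert (out[:, :, 1] == 0).all()
        np.testing.assert_array_equal(out[:, :, [0, 2, 3]], t[:, :, [0, 2, 3]])

    def test_elementwise_product_oracle(self, rng):
        t = rng.random((3, 6, 5))
        gates = rng.random(5)
        out = scale(t, gates)
        for r in range(3):
            for c in range(6):
                for ch in range(5):
                    assert out[r, c, ch] == t[r, c, ch] * gates[ch]

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="gate length"):
            scale(rng.random((3, 6, 4)), np.ones(5))


class TestExcitation:
    def test_zero_weights_give_half_gates(self):
        se = SqueezeExcite(18, 4, 2, np.random.default_rng(0))
        for p in se.params:
            p[...] = 0.0
        gates = se.gates(np.random.default_rng(1).random((2, 72)))
        np.testing.assert_allclose(gates, 0.5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        se = SqueezeExcite(18, 8, 2, np.random.default_rng(3))
        gates = se.gates(rng.random((5, 144)))
        assert (gates > 0).all() and (gates < 1).all()

    def test_hand_computed_two_channel_toy(self):
        # 2 channels, bottleneck 1; W1 = [[1], [-1]]^T, W2 = [[2, -3]]
        se = SqueezeExcite(1, 2, 2, np.random.default_rng(0))
        se.fc1.W[...] = np.array([[1.0], [-1.0]])
        se.fc1.b[...] = 0.5
        se.fc2.W[...] = np.array([[2.0, -3.0]])
        se.fc2.b[...] = np.array([0.1, -0.2])
        pooled = np.array([[0.8, 0.3]])
        h = max(0.0, 0.8 * 1.0 + 0.3 * (-1.0) + 0.5)       # = 1.0
        expected = 1 / (1 + np.exp(-(np.array([2.0, -3.0]) * h
                                     + np.array([0.1, -0.2]))))
        gates = se.gates(pooled)  # positions=1: pooled equals the input
        np.testing.assert_allclose(gates.ravel(), expected, atol=1e-12)

    def test_within_channel_permutation_invariance(self, rng):
        """Pooling makes gates invariant to shuffling values inside a channel."""
        se = SqueezeExcite(18, 4, 2, np.random.default_rng(5))
        x = rng.random(72)
        t = x.reshape(18, 4)
        perm = rng.permutation(18)
        np.testing.assert_allclose(se.gates(x.reshape(1, -1)),
                                   se.gates(t[perm].reshape(1, -1)),
                                   atol=1e-12)


class TestBuildAndForward:
    def test_head_widths(self):
        cfg = ClockConfig(channels=4, se_reduction=2)
        net = build_network(72, cfg, "perseclock", 0)
        linears = [l for l in net.layers if isinstance(l, Linear)]
        assert [l.W.shape[1] for l in linears] == [32, 32, 32, 32, 1]

    def test_same_seed_identical_init(self):
        cfg = ClockConfig(channels=4, se_reduction=2)
        a = build_network(72, cfg, "perseclock", 42)
        b = build_network(72, cfg, "perseclock", 42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_plain_mlp_has_no_excitation(self):
        cfg = ClockConfig(channels=4, se_reduction=2)
        net = build_network(72, cfg, "plain_mlp", 0)
        assert not any(isinstance(l, SqueezeExcite) for l in net.layers)

    def test_zeroed_excitation_halves_input(self, rng):
        """With all SE params zero, every gate is 0.5, so the attention model
        equals the plain head applied to 0.5 * x."""
        cfg = ClockConfig(channels=4, se_reduction=2, dropout_rate=0.0)
        se_net = build_network(72, cfg, "perseclock", 9)
        mlp_net = build_network(72, cfg, "plain_mlp", 10)
        for p in se_net.layers[0].params:
            p[...] = 0.0
        # copy head parameters across
        for a, b in zip(se_net.layers[1:], mlp_net.layers):
            for pa, pb in zip(a.params, b.params):
                pb[...] = pa
        x = rng.random((3, 72))
        np.testing.assert_allclose(se_net.forward(x), mlp_net.forward(0.5 * x),
                                   atol=1e-10)

    def test_eval_forward_deterministic(self, rng):
        cfg = ClockConfig(channels=4, se_reduction=2)
        net = build_network(72, cfg, "perseclock", 1)
        x = rng.random((2, 72))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_continuity_in_input(self, rng):
        """Perturbing one coordinate by eps changes the output by O(eps)."""
        cfg = ClockConfig(channels=4, se_reduction=2)
        net = build_network(72, cfg, "perseclock", 2)
        x = rng.random((1, 72))
        base = net.forward(x)[0, 0]
        for eps in (1e-3, 1e-5):
            xp = x.copy()
            xp[0, 17] += eps
            assert abs(net.forward(xp)[0, 0] - base) < 1e3 * eps

    def test_forward_rejects_non_finite(self, tiny_cohort):
        bm, meta, _ = tiny_cohort
        est = PerSEClockRegressor(channels=4, se_reduction=2, max_epochs=2,
                                  patience=1, batch_size=128, random_state=0)
        est.fit(bm.values, meta["age"].to_numpy())
        x = bm.values[0].copy()
        x[0] = np.nan
        with pytest.raises(ValueError):
            forward(x, est)


class TestGradients:
    @pytest.mark.parametrize("variant", ["perseclock", "plain_mlp"])
    def test_backprop_matches_finite_differences(self, rng, variant):
        """End-to-end analytic gradients vs central differences (dropout off,
        batch statistics active)."""
        cfg = ClockConfig(channels=3, se_reduction=2, hidden_width=4,
                          hidden_depth=2, dropout_rate=0.0)
        net = build_network(54, cfg, variant, 11)
        x = rng.random((6, 54))
        y = rng.uniform(0, 80, 6)

        def loss():
            pred = net.forward(x, training=True).ravel()
            return float(np.mean((pred - y) ** 2))

        base_pred = net.forward(x, training=True).ravel()
        net.backward((2.0 * (base_pred - y) / len(y)).reshape(-1, 1))
        analytic = [g.copy() for g in net.gradients()]
        params = net.parameters()
        eps = 1e-6
        for p, g in zip(params, analytic):
            flat_p, flat_g = p.ravel(), g.ravel()
            for k in rng.choice(flat_p.size, size=min(4, flat_p.size),
                                replace=False):
                orig = flat_p[k]
                flat_p[k] = orig + eps
                lp = loss()
                flat_p[k] = orig - eps
                lm = loss()
                flat_p[k] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(
                    flat_g[k], rel=1e-4, abs=1e-7)

    def test_no_dead_subgraph(self, rng):
        """Every parameter accumulates nonzero gradient over a few random batches."""
        cfg = ClockConfig(channels=4, se_reduction=2, dropout_rate=0.0)
        net = build_network(72, cfg, "perseclock", 0)
        total = [np.zeros_like(g) for g in net.gradients()]
        for _ in range(5):
            x = rng.random((16, 72))
            y = rng.uniform(0, 100, 16)
            pred = net.forward(x, training=True).ravel()
            net.backward((2.0 * (pred - y) / 16).reshape(-1, 1))
            for t, g in zip(total, net.gradients()):
                t += np.abs(g)
        assert all((t > 0).all() for t in total)


class TestEstimatorApi:
    def test_sklearn_params_round_trip(self):
        est = PerSEClockRegressor(channels=24, learning_rate=0.01)
        params = est.get_params()
        assert params["channels"] == 24
        est.set_params(learning_rate=0.02)
        assert est.learning_rate == 0.02

    def test_indivisible_input_length_is_hard_error(self, rng):
        est = PerSEClockRegressor(channels=None, max_epochs=1, patience=1)
        X = rng.random((30, 71))  # 71 not divisible by 18
        with pytest.raises(ValueError, match="divisible"):
            est.fit(X, rng.uniform(0, 90, 30))

    def test_functional_excitation_matches_channel_gates(self, tiny_cohort):
        bm, meta, _ = tiny_cohort
        est = PerSEClockRegressor(channels=4, se_reduction=2, max_epochs=2,
                                  patience=1, batch_size=128, random_state=0)
        est.fit(bm.values, meta["age"].to_numpy())
        x = bm.values[0]
        cfg = ClockConfig(channels=4, se_reduction=est.se_reduction)
        pooled = global_average_pool(reshape_to_blocks(x, cfg))
        np.testing.assert_allclose(excitation(pooled, est),
                                   est.channel_gates(x[None])[0], atol=1e-12)

    def test_build_model_factory(self):
        est = build_model(ClockConfig(channels=4, se_reduction=2),
                          "plain_mlp", seed=3)
        assert isinstance(est, MLPClockRegressor)
        assert est.random_state == 3


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_cohort):
        bm, meta, _ = tiny_cohort
        est = PerSEClockRegressor(channels=4, se_reduction=2, max_epochs=3,
                                  patience=3, batch_size=128, random_state=0)
        est.fit(bm.values, meta["age"].to_numpy())
        path = tmp_path / "ckpt.npz"
        save_checkpoint(est, path, locus_ids=list(bm.locus_ids))
        loaded = load_checkpoint(path)
        np.testing.assert_allclose(loaded.predict(bm.values[:20]),
                                   est.predict(bm.values[:20]), atol=1e-12)
        assert loaded.locus_ids_ == list(bm.locus_ids)
        assert loaded.best_val_loss_ == est.best_val_loss_

    def test_conflicting_config_refused(self, tmp_path, tiny_cohort):
        bm, meta, _ = tiny_cohort
        est = MLPClockRegressor(channels=4, se_reduction=4, max_epochs=2,
                                patience=2, batch_size=128, random_state=0)
        est.fit(bm.values, meta["age"].to_numpy())
        path = tmp_path / "ckpt.npz"
        save_checkpoint(est, path)
        with pytest.raises(ValueError, match="conflict"):
            load_checkpoint(path, expected_params={"hidden_width": 64})
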