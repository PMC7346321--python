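"""EnDCNN layer semantics, residual identity, cost accounting and training."""

import numpy as np
import pytest

from endcnn.classifier import (
    EnDCNNConfig,
    EnDCNNModel,
    classifier_learning_rate,
    conv_block,
    conv_preact,
    count_macs,
    cumulative_stride,
    downsample,
    final_pool,
    receptive_field,
    region_embed,
    train_classifier,
)


class TestRegionEmbed:
    def test_k1_zero_bias_selects_weight_column(self, rng):
        v, m = 5, 3
        W = rng.normal(size=(m, v))
        idx = np.array([2, 4, 0])
        out = region_embed(idx, W, np.zeros(m), k=1, v=v)
        np.testing.assert_allclose(out, W[:, idx])

    def test_input_dimension_is_k_times_v(self):
        v, m, k = 4, 2, 7
        W = np.zeros((m, k * v))
        out = region_embed(np.zeros(3, dtype=int), W, np.zeros(m), k=k, v=v)
        assert out.shape == (m, 3)
        with pytest.raises(ValueError):
            region_embed(np.zeros(3, dtype=int), np.zeros((m, 3 * v)), np.zeros(m), k=k, v=v)

    def test_hand_windowed_products(self, rng):
        # k=3, v=4, m=2 over a 5-token input, PAD index 0 beyond edges
        v, m, k = 4, 2, 3
        W = rng.normal(size=(m, k * v))
        b = rng.normal(size=m)
        idx = np.array([1, 3, 2, 0, 1])
        out = region_embed(idx, W, b, k=k, v=v)
        for t in range(5):
            x = np.zeros(k * v)
            for j, off in enumerate(range(-1, 2)):
                pos = t + off
                tok = idx[pos] if 0 <= pos < 5 else 0
                x[j * v + tok] = 1.0
            np.testing.assert_allclose(out[:, t], W @ x + b, atol=1e-12)


class TestConvPreact:
    def test_zero_weights_output_bias_everywhere(self, rng):
        x = rng.normal(size=(3, 6))
        b = rng.normal(size=3)
        out = conv_preact(x, np.zeros((3, 9)), b)
        np.testing.assert_allclose(out, np.tile(b[:, None], (1, 6)))

    def test_rectifier_kills_negative_input(self, rng):
        x = -np.abs(rng.normal(size=(2, 5))) - 0.1
        W = rng.normal(size=(2, 6))
        out = conv_preact(x, W, np.zeros(2))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_position_scalar_hand_check(self):
        # m=1, ks=3, one position: window is [0, x, 0] after zero padding
        x = np.array([[0.7]])
        W = np.array([[2.0, -3.0, 5.0]])
        b = np.array([0.25])
        out = conv_preact(x, W, b)
        assert out[0, 0] == pytest.approx(-3.0 * 0.7 + 0.25)

    def test_activation_applied_before_weighting(self):
        # negative entries must be zeroed before the linear map: otherwise
        # the sign of W would flip them into the output
        x = np.array([[-1.0, 2.0]])
        W = np.array([[0.0, 1.0, 0.0]])
        out = conv_preact(x, W, np.zeros(1))
        np.testing.assert_allclose(out, [[0.0, 2.0]])


class TestConvBlock:
    def test_zero_block_is_identity(self, rng):
        x = rng.normal(size=(4, 7))
        z = np.zeros((4, 12))
        out = conv_block(x, z, np.zeros(4), z, np.zeros(4))
        np.testing.assert_array_equal(out, x)

    def test_shape_preserved_for_random_shapes(self, rng):
        for m, L in ((1, 1), (3, 2), (5, 17)):
            x = rng.normal(size=(m, L))
            W = rng.normal(size=(m, 3 * m))
            out = conv_block(x, W, np.zeros(m), W, np.zeros(m))
            assert out.shape == x.shape

    def test_hand_z_plus_f_of_z(self):
        x = np.array([[1.0, -2.0, 3.0]])
        W1 = np.array([[1.0, 1.0, 1.0]])
        b1 = np.array([0.0])
        W2 = np.array([[0.0, 2.0, 0.0]])
        b2 = np.array([-1.0])
        h1 = conv_preact(x, W1, b1)
        expected = x + conv_preact(h1, W2, b2)
        np.testing.assert_allclose(conv_block(x, W1, b1, W2, b2), expected)


class TestPooling:
    def test_length_eight_halves_to_four(self, rng):
        assert downsample(rng.normal(size=(3, 8))).shape == (3, 4)

    def test_length_one_survives(self):
        x = np.array([[7.0], [1.0]])
        np.testing.assert_array_equal(downsample(x), x)

    def test_hand_windows_with_neg_inf_padding(self):
        x = np.array([[1.0, 5.0, 2.0, 4.0, 3.0]])
        np.testing.assert_array_equal(downsample(x), [[5.0, 5.0, 4.0]])

    def test_odd_lengths_round_up(self, rng):
        for L, expect in ((1, 1), (2, 1), (3, 2), (7, 4), (9, 5)):
            assert downsample(rng.normal(size=(2, L))).shape[1] == expect

    def test_final_pool_is_componentwise_max(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        np.testing.assert_array_equal(final_pool(x), [1.0, 2.0])

    def test_final_pool_permutation_invariant(self, rng):
        x = rng.normal(size=(4, 9))
        perm = rng.permutation(9)
        np.testing.assert_array_equal(final_pool(x), final_pool(x[:, perm]))


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        model = EnDCNNModel(6, EnDCNNConfig(region_size=3, feature_maps=4, depth=5))
        for _ in range(5):
            units = rng.integers(0, 6, size=rng.integers(1, 30))
            p = model.forward(units)
            assert p.shape == (2,)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)

    def test_all_zero_weights_give_even_odds(self):
        model = EnDCNNModel(5, EnDCNNConfig(region_size=3, feature_maps=4, depth=3),
                            zero_blocks=True)
        for k in model.params:
            model.params[k][:] = 0.0
        np.testing.assert_allclose(model.forward(np.array([1, 2, 3])), [0.5, 0.5])

    def test_empty_unit_sequence_rejected(self):
        model = EnDCNNModel(5, EnDCNNConfig(region_size=3, feature_maps=4, depth=3))
        with pytest.raises(ValueError):
            model.forward(np.array([], dtype=int))

    def test_tiny_model_end_to_end_hand_computation(self):
        # m=2, 1 block, k=1, v=3, length 4: trace the whole path by hand
        cfg = EnDCNNConfig(region_size=1, feature_maps=2, depth=3)
        model = EnDCNNModel(3, cfg, seed=0)
        units = np.array([0, 1, 2, 1])
        p = model.params
        x = p["Wr"][:, units] + p["br"][:, None]
        z = x + conv_preact(conv_preact(x, p["W0a"], p["b0a"]), p["W0b"], p["b0b"])
        vpool = z.max(axis=1)
        logits = p["Wh"] @ vpool + p["bh"]
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(model.forward(units), e / e.sum(), atol=1e-12)

    def test_gradients_match_finite_differences(self):
        cfg = EnDCNNConfig(region_size=3, feature_maps=4, depth=7)
        model = EnDCNNModel(6, cfg, seed=3)
        units = np.arange(1, 12) % 6
        _, cache = model._forward_cache(units)
        grads = model._backward(cache, 1)
        eps = 1e-6
        for name, A in model.params.items():
            num = np.zeros_like(A)
            for idx in np.ndindex(A.shape):
                A[idx] += eps
                up = -np.log(model.forward(units)[1])
                A[idx] -= 2 * eps
                dn = -np.log(model.forward(units)[1])
                A[idx] += eps
                num[idx] = (up - dn) / (2 * eps)
            np.testing.assert_allclose(num, grads[name], atol=1e-5,
                                       err_msg=f"gradient mismatch in {name}")


class TestResidualStructure:
    @pytest.mark.parametrize("depth", [3, 7, 15])
    def test_zero_blocks_leave_output_unchanged_by_depth(self, depth):
        # with all block weights zero, output depends only on the region
        # embedding and head: deepening adds nothing
        shallow = EnDCNNModel(6, EnDCNNConfig(region_size=3, feature_maps=4, depth=3),
                              seed=7, zero_blocks=True)
        deep = EnDCNNModel(6, EnDCNNConfig(region_size=3, feature_maps=4, depth=depth),
                           seed=7, zero_blocks=True)
        for k in ("Wr", "br", "Wh", "bh"):
            deep.params[k] = shallow.params[k].copy()
        units = np.array([1, 2, 3, 4, 5, 1, 2, 3])
        np.testing.assert_allclose(shallow.forward(units), deep.forward(units),
                                   atol=1e-12)

    @pytest.mark.parametrize("k", [1, 7, 14])
    @pytest.mark.parametrize("blocks", [1, 4, 12])
    def test_every_shortcut_addition_is_shape_equal(self, k, blocks):
        cfg = EnDCNNConfig(region_size=k, feature_maps=4, depth=1 + 2 * blocks)
        model = EnDCNNModel(6, cfg, seed=0)
        trace = []
        model.forward(np.arange(1, 30) % 6, trace=trace)
        assert len(trace) == blocks
        for z_shape, fz_shape in trace:
            assert z_shape == fz_shape


class TestCostAccounting:
    def test_consecutive_block_ratio_is_half_at_powers_of_two(self):
        cfg = EnDCNNConfig()
        for L in (64, 256, 1024, 8192):
            macs = count_macs(cfg, L)
            for a, b in zip(macs, macs[1:]):
                assert b / a == 0.5

    def test_total_bounded_by_twice_first_block(self):
        cfg = EnDCNNConfig()
        for L in (64, 128, 1024, 8192):
            macs = count_macs(cfg, L)
            assert sum(macs) <= 2 * macs[0]

    def test_one_block_network_total_equals_first(self):
        macs = count_macs(EnDCNNConfig(depth=3), 100)
        assert len(macs) == 1

    def test_ratio_approaches_half_generally(self):
        # ceil effects keep the ratio within 1/2 + o(1) at realistic lengths
        cfg = EnDCNNConfig(depth=25)
        for L in (1000, 5000, 10000):
            macs = count_macs(cfg, L)
            for level, (a, b) in enumerate(zip(macs, macs[1:])):
                if macs[level + 1] > cfg.kernel_size * cfg.feature_maps**2 * 8:
                    assert b / a <= 0.5 + 0.05


class TestReceptiveField:
    def test_single_block_no_pooling_hand_value(self):
        assert receptive_field(EnDCNNConfig(region_size=7), 0) == 11

    def test_growth_ratio_approaches_two(self):
        cfg = EnDCNNConfig()
        rs = [receptive_field(cfg, L) for L in range(12)]
        for L in range(3, 11):
            ratio = rs[L + 1] / rs[L]
            assert 1.8 <= ratio <= 2.0

    def test_cumulative_stride_is_power_of_two(self):
        for L in range(11):
            assert cumulative_stride(L) == 2**L


@pytest.fixture(scope="module")
def toy_dataset():
    rng = np.random.default_rng(0)
    data = []
    for i in range(10):
        # class 1 iff token 3 occurs
        has = i % 2
        units = rng.integers(4, 7, size=14)
        if has:
            units[rng.integers(14)] = 3
        data.append((units, has))
    return data


class TestTraining:
    def test_memorizes_toy_set(self, toy_dataset):
        cfg = EnDCNNConfig(region_size=3, feature_maps=8, depth=5, epochs=200,
                           batch_size=4, unit_permute=False, token_dropout=0.0)
        model, losses = train_classifier(toy_dataset, cfg, vocab_size=7, seed=1)
        preds = [int(np.argmax(model.forward(u))) for u, _ in toy_dataset]
        assert preds == [l for _, l in toy_dataset]
        assert losses[0] > losses[-1]

    def test_seed_determinism(self, toy_dataset):
        cfg = EnDCNNConfig(region_size=3, feature_maps=4, depth=3, epochs=3,
                           batch_size=4)
        a, la = train_classifier(toy_dataset, cfg, vocab_size=7, seed=9)
        b, lb = train_classifier(toy_dataset, cfg, vocab_size=7, seed=9)
        assert la == lb
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_single_class_warns_but_trains(self):
        data = [(np.array([1, 2, 3]), 0) for _ in range(4)]
        cfg = EnDCNNConfig(region_size=3, feature_maps=4, depth=3, epochs=1,
                           batch_size=2)
        with pytest.warns(UserWarning, match="single class"):
            train_classifier(data, cfg, vocab_size=4, seed=0)

    def test_learning_rate_schedule(self):
        cfg = EnDCNNConfig()
        assert classifier_learning_rate(cfg, 0) == pytest.approx(0.001)
        assert classifier_learning_rate(cfg, 500) == pytest.approx(0.001 * 0.99)
        assert classifier_learning_rate(cfg, 1250) == pytest.approx(
            0.001 * 0.99 ** 2.5)

    def test_save_load_round_trip(self, toy_dataset, tmp_path):
        cfg = EnDCNNConfig(region_size=3, feature_maps=4, depth=3, epochs=1,
                           batch_size=4)
        model, _ = train_classifier(toy_dataset, cfg, vocab_size=7, seed=0)
        model.save(tmp_path / "clf.npz")
        loaded = EnDCNNModel.load(tmp_path / "clf.npz")
        u = toy_dataset[0][0]
        np.testing.assert_allclose(loaded.forward(u), model.forward(u))
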