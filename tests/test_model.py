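"""Transformer encoder: contracts, gradients, masking, losses, checkpoints."""

import numpy as np
import pytest

from ppgvitals.model import (
    ModelConfig,
    TimeSeriesTransformer,
    destandardize,
    load_checkpoint,
    mask_for_mlm,
    mlm_loss,
    regression_loss,
    save_checkpoint,
    standardize,
)

TINY = ModelConfig(
    n_layers=2, d_model=8, n_heads=2, d_ff=12, head_hidden=6,
    dropout=0.0, max_len=16, n_channels=3, targets=("ASBP", "ADBP"),
)


class TestStandardize:
    def test_zero_mean_unit_sd_per_channel(self, rng):
        x = rng.normal(3.0, 5.0, size=(4, 200))
        z, stats = standardize(x)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-6)

    def test_all_zero_channel_passes_through(self):
        x = np.zeros((2, 50))
        x[0] = np.sin(np.arange(50))
        z, _ = standardize(x)
        np.testing.assert_array_equal(z[1], np.zeros(50))

    def test_round_trip(self, rng):
        x = rng.normal(10.0, 2.0, size=(3, 100))
        z, stats = standardize(x)
        np.testing.assert_allclose(destandardize(z, stats), x, atol=1e-6)

    def test_padded_region_excluded_from_stats(self, rng):
        x = rng.normal(size=(2, 20))
        pad = np.zeros(20, bool)
        pad[10:] = True
        z, stats = standardize(x, pad)
        np.testing.assert_allclose(x[:, :10].mean(axis=1), stats["mean"], atol=1e-12)
        np.testing.assert_array_equal(z[:, 10:], 0.0)


class TestEmbedding:
    def test_scalar_projection_example(self):
        cfg = ModelConfig(
            n_layers=0, d_model=1, n_heads=1, d_ff=1, head_hidden=1,
            dropout=0.0, max_len=4, n_channels=1, targets=("ASBP",),
        )
        m = TimeSeriesTransformer(cfg, seed=0)
        m.params["W_p"] = np.array([[2.0]])
        m.params["b_p"] = np.array([1.0])
        m.params["W_pos"] = np.zeros((4, 1))
        enc, _ = m.encode(np.array([[[3.0]]]))
        assert enc[0, 0, 0] == pytest.approx(7.0)  # 2*3 + 1

    def test_zero_parameters_give_zero_embedding(self):
        cfg = ModelConfig(
            n_layers=0, d_model=4, n_heads=1, d_ff=4, head_hidden=4,
            dropout=0.0, max_len=6, n_channels=2, targets=("ASBP",),
        )
        m = TimeSeriesTransformer(cfg, seed=0)
        for k in ("W_p", "b_p", "W_pos"):
            m.params[k] = np.zeros_like(m.params[k])
        enc, _ = m.encode(np.ones((1, 2, 6)))
        np.testing.assert_array_equal(enc, 0.0)

    def test_positional_encoding_breaks_time_permutation(self, rng):
        cfg = ModelConfig(
            n_layers=0, d_model=4, n_heads=1, d_ff=4, head_hidden=4,
            dropout=0.0, max_len=8, n_channels=2, targets=("ASBP",),
        )
        m = TimeSeriesTransformer(cfg, seed=1)
        x = rng.normal(size=(1, 2, 8))
        perm = rng.permutation(8)
        enc_a, _ = m.encode(x)
        enc_b, _ = m.encode(x[:, :, perm])
        assert not np.allclose(enc_a[:, perm, :], enc_b)

    def test_length_beyond_max_len_rejected(self):
        m = TimeSeriesTransformer(TINY, seed=0)
        with pytest.raises(ValueError, match="max_len"):
            m.encode(np.zeros((1, 3, 17)))


class TestAttention:
    def test_rows_sum_to_one_and_ignore_padded_keys(self, rng):
        m = TimeSeriesTransformer(TINY, seed=0)
        x = rng.normal(size=(2, 3, 10))
        pad = np.zeros((2, 10), bool)
        pad[0, 7:] = True
        for A in m.attention_matrices(x, pad):
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-9)
            assert np.max(A[0, :, :, 7:]) == 0.0

    def test_single_key_attention_is_identity_weight(self, rng):
        m = TimeSeriesTransformer(TINY, seed=0)
        x = rng.normal(size=(1, 3, 10))
        pad = np.ones((1, 10), bool)
        pad[0, 0] = False
        A = m.attention_matrices(x, pad)[0]
        np.testing.assert_allclose(A[0, :, :, 0], 1.0, atol=1e-12)

    def test_two_position_toy_matches_brute_force_softmax(self, rng):
        """One head, one layer: compare against an explicit Q/K/V softmax."""
        cfg = ModelConfig(
            n_layers=1, d_model=4, n_heads=1, d_ff=4, head_hidden=4,
            dropout=0.0, max_len=2, n_channels=2, targets=("ASBP",),
        )
        m = TimeSeriesTransformer(cfg, seed=3)
        Z = rng.normal(size=(1, 2, 4))
        out, _ = m._attention(Z, None, 0, False, None)
        p = m.params
        Q = Z[0] @ p["L0.Wq"]
        K = Z[0] @ p["L0.Wk"]
        V = Z[0] @ p["L0.Wv"]
        S = Q @ K.T / 2.0  # sqrt(d_k) = 2
        E = np.exp(S - S.max(axis=1, keepdims=True))
        A = E / E.sum(axis=1, keepdims=True)
        expected = (A @ V) @ p["L0.Wo"] + p["L0.bo"]
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_all_padded_sample_rejected(self):
        m = TimeSeriesTransformer(TINY, seed=0)
        with pytest.raises(ValueError, match="padded"):
            m.encode(np.zeros((1, 3, 4)), np.ones((1, 4), bool))

    def test_sqrt_len_scaling_variant_changes_scores(self, rng):
        x = rng.normal(size=(1, 3, 10))
        a = TimeSeriesTransformer(TINY, seed=5).predict(x)
        cfg2 = ModelConfig(**{**TINY.__dict__, "attn_scale": "sqrt_len"})
        b = TimeSeriesTransformer(cfg2, seed=5).predict(x)
        assert not np.allclose(a, b)


class TestRegressionHead:
    def test_zero_network_outputs_bias(self):
        m = TimeSeriesTransformer(TINY, seed=0)
        for k, v in m.params.items():
            m.params[k] = np.zeros_like(v)
        m.params["head.b2"] = np.array([4.5, -1.0])
        y = m.predict(np.zeros((3, 3, 10)))
        np.testing.assert_allclose(y, np.tile([4.5, -1.0], (3, 1)))

    def test_output_count_matches_targets(self, rng):
        x = rng.normal(size=(2, 3, 8))
        assert TimeSeriesTransformer(TINY, seed=0).predict(x).shape == (2, 2)
        single = ModelConfig(**{**TINY.__dict__, "targets": ("SpO2",)})
        assert TimeSeriesTransformer(single, seed=0).predict(x).shape == (2, 1)

    def test_prediction_invariant_to_padded_values(self, rng):
        m = TimeSeriesTransformer(TINY, seed=2)
        x = rng.normal(size=(1, 3, 12))
        pad = np.zeros((1, 12), bool)
        pad[0, 9:] = True
        y1 = m.predict(x, pad)
        x2 = x.copy()
        x2[:, :, 9:] = rng.normal(size=(1, 3, 3)) * 100
        y2 = m.predict(x2, pad)
        np.testing.assert_allclose(y1, y2, atol=1e-6)

    def test_padding_invariance_vs_native_length(self, rng):
        m = TimeSeriesTransformer(TINY, seed=4)
        x = rng.normal(size=(1, 3, 9))
        y_native = m.predict(x)
        xp = np.zeros((1, 3, 16))
        xp[:, :, :9] = x
        pad = np.ones((1, 16), bool)
        pad[0, :9] = False
        y_padded = m.predict(xp, pad)
        np.testing.assert_allclose(y_native, y_padded, atol=1e-5)


class TestGradients:
    def _numeric_check(self, model, loss_fn, grads, n_per_param=4, eps=1e-6, tol=1e-5):
        rng = np.random.default_rng(0)
        for name, g in grads.items():
            flat = model.params[name].ravel()
            for i in rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_fn()
                flat[i] = old - eps
                lm = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = g.ravel()[i]
                assert abs(num - ana) <= tol * max(1.0, abs(num), abs(ana)), name

    def test_regression_backward_matches_numerical(self, rng):
        m = TimeSeriesTransformer(TINY, seed=0)
        x = rng.normal(size=(2, 3, 7))
        pad = np.zeros((2, 7), bool)
        pad[1, 5:] = True
        y = rng.normal(size=(2, 2))
        yh, cache = m.predict(x, pad, return_cache=True)
        _, dg = regression_loss(yh, y, return_grad=True)
        grads = m.backward_regression(dg, cache)
        self._numeric_check(m, lambda: regression_loss(m.predict(x, pad), y), grads)

    def test_mlm_backward_matches_numerical(self, rng):
        m = TimeSeriesTransformer(TINY, seed=1)
        x = rng.normal(size=(2, 3, 7))
        mask = np.zeros((2, 7), bool)
        mask[:, 2:4] = True
        rec, cache = m.reconstruct(x, return_cache=True, mlm_mask=mask)
        _, dg = mlm_loss(rec, x, mask, return_grad=True)
        grads = m.backward_mlm(dg, cache)
        self._numeric_check(
            m, lambda: mlm_loss(m.reconstruct(x, mlm_mask=mask), x, mask), grads
        )
        assert np.any(grads["mlm.token"] != 0)

    def test_positional_encodings_receive_gradient(self, rng):
        """W_pos and W_p must move under optimization (they are learnable)."""
        m = TimeSeriesTransformer(TINY, seed=0)
        x = rng.normal(size=(2, 3, 7))
        y = rng.normal(size=(2, 2))
        yh, cache = m.predict(x, return_cache=True)
        _, dg = regression_loss(yh, y, return_grad=True)
        grads = m.backward_regression(dg, cache)
        assert np.any(grads["W_pos"][:7] != 0)
        assert np.any(grads["W_p"] != 0)
        assert np.all(grads["W_pos"][7:] == 0)  # unused positions untouched


class TestMasking:
    def test_zero_ratio_masks_nothing(self, rng):
        x = rng.normal(size=(4, 100))
        xm, mask = mask_for_mlm(x, ratio=0.0, seed=0)
        assert not mask.any()
        np.testing.assert_array_equal(xm, x)

    def test_masked_count_concentrates_near_ratio(self, rng):
        counts = []
        x = rng.normal(size=(4, 2500))
        for seed in range(100):
            _, mask = mask_for_mlm(x, ratio=0.15, mean_span=3.0, seed=seed)
            counts.append(mask.sum())
        assert all(300 <= c <= 450 for c in counts)

    def test_masked_positions_are_zeroed_all_channels(self, rng):
        x = rng.normal(size=(3, 200)) + 5
        xm, mask = mask_for_mlm(x, ratio=0.2, seed=1)
        assert mask.sum() > 0
        np.testing.assert_array_equal(xm[:, mask], 0.0)
        np.testing.assert_array_equal(xm[:, ~mask], x[:, ~mask])

    def test_padded_positions_never_masked(self, rng):
        x = rng.normal(size=(2, 100))
        pad = np.zeros(100, bool)
        pad[60:] = True
        for seed in range(20):
            _, mask = mask_for_mlm(x, ratio=0.3, seed=seed, pad_mask=pad)
            assert not mask[60:].any()

    def test_ratio_one_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            mask_for_mlm(np.zeros((2, 10)), ratio=1.0)


class TestLosses:
    def test_perfect_prediction_zero_loss(self):
        y = np.array([[1.0, 2.0]])
        assert regression_loss(y, y) == 0.0

    def test_two_sample_hand_arithmetic(self):
        # errors [1, -1] over a batch of 2 -> (1 + 1)/2 = 1
        assert regression_loss(np.array([[1.0], [-1.0]]), np.zeros((2, 1))) == 1.0

    def test_mlm_loss_ignores_unmasked_positions(self, rng):
        x = rng.normal(size=(2, 100))
        pred = rng.normal(size=(2, 100))
        mask = np.zeros(100, bool)
        mask[10:20] = True
        base = mlm_loss(pred, x, mask)
        pred2 = pred.copy()
        pred2[:, ~mask] += 100
        assert mlm_loss(pred2, x, mask) == base

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            mlm_loss(np.zeros((2, 10)), np.zeros((2, 10)), np.zeros(10, bool))


class TestCheckpoints:
    def test_round_trip_preserves_config_and_predictions(self, tmp_path, rng):
        m = TimeSeriesTransformer(TINY, seed=0)
        x = rng.normal(size=(1, 3, 10))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path, extra={"note": "unit"})
        m2, extra = load_checkpoint(path)
        assert m2.config == m.config
        assert extra["note"] == "unit"
        np.testing.assert_array_equal(m.predict(x), m2.predict(x))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(d_model=10, n_heads=4)
    with pytest.raises(ValueError, match="attn_scale"):
        ModelConfig(attn_scale="none")
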