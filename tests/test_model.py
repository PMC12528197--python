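"""Transformer core: positional encoding, attention stochasticity, mask
identities, brute-force oracles, gradient checks, equivariance."""

import math
import warnings

import numpy as np
import pytest

from conftest import tiny_config
from eegformer.model import (
    EEGTransformer,
    ModelConfig,
    classify,
    mask_loss,
    masked_attention_weights,
    positional_encoding,
    spatial_attention,
)


class TestPositionalEncoding:
    def test_matches_closed_form_scalar_by_scalar(self):
        seq_len, d = 16, 256
        pe = positional_encoding(seq_len, d)
        for pos in (0, 1, 7, 15):
            for i in (0, 1, 64, 127):
                angle = pos / 10000 ** (2 * i / d)
                assert pe[pos, 2 * i] == pytest.approx(math.sin(angle), abs=1e-12)
                assert pe[pos, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-12)

    def test_position_zero_row(self):
        pe = positional_encoding(8, 32)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)

    def test_range_and_odd_dim(self):
        pe = positional_encoding(50, 64)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestMaskedAttention:
    def test_uniform_scores_give_uniform_weights(self):
        raw, masked = masked_attention_weights(np.zeros((2, 2)))
        np.testing.assert_array_equal(raw, 0.5)
        np.testing.assert_array_equal(masked, 0.5)

    def test_all_ones_mask_is_bitwise_identity(self, rng):
        scores = rng.standard_normal((3, 2, 4, 4))
        raw, masked = masked_attention_weights(scores, np.ones((4, 4)))
        assert np.array_equal(raw, masked)

    def test_three_by_three_hand_oracle(self):
        scores = np.array([[0.5, -1.0, 2.0], [0.0, 0.0, 1.0], [-2.0, 0.3, 0.1]])
        mask = np.array([[1.0, 0.2, 0.7], [0.5, 1.0, 0.1], [0.9, 0.9, 0.9]])
        raw, masked = masked_attention_weights(scores, mask)
        # independent brute force: softmax -> elementwise product -> renormalize
        for i in range(3):
            exps = [math.exp(scores[i, j]) for j in range(3)]
            soft = [e / sum(exps) for e in exps]
            prod = [s * m for s, m in zip(soft, mask[i])]
            renorm = [p / sum(prod) for p in prod]
            np.testing.assert_allclose(raw[i], soft, atol=1e-6)
            np.testing.assert_allclose(masked[i], renorm, atol=1e-6)

    def test_fully_masked_row_falls_back_to_uniform(self):
        scores = np.zeros((2, 2))
        mask = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="fully-masked"):
            _, masked = masked_attention_weights(scores, mask)
        np.testing.assert_allclose(masked[0], 0.5)

    def test_rows_stochastic_over_random_configs(self):
        """Temporal raw/masked and spatial rows sum to 1 within 1e-6
        across many random seeded configurations."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            heads = int(r.choice([1, 2, 4]))
            d = heads * int(r.choice([2, 4]))
            cfg = ModelConfig(
                n_layers=int(r.integers(1, 3)), n_heads=heads, d_model=d,
                d_ff=2 * d, n_classes=2, n_channels=int(r.integers(1, 4)),
                seq_len=int(r.integers(2, 6)), frame_dim=3, seed=seed,
            )
            model = EEGTransformer(cfg)
            frames = r.standard_normal((2, cfg.n_channels, cfg.seq_len, 3))
            res = model.forward(frames, collect_attention=True)
            for a in res.temporal_raw + res.temporal_masked:
                np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)
                assert np.all(a >= 0) and np.all(a <= 1 + 1e-12)
            np.testing.assert_allclose(res.spatial.sum(axis=-1), 1.0, atol=1e-6)
            np.testing.assert_allclose(res.probs.sum(axis=-1), 1.0, atol=1e-6)


class TestMaskLoss:
    def test_open_mask_gives_zero(self, rng):
        a = masked_attention_weights(rng.standard_normal((2, 3, 4, 4)))[0]
        assert mask_loss(a, np.ones((4, 4))) == pytest.approx(0.0, abs=1e-12)

    def test_closed_mask_gives_row_count(self, rng):
        a = masked_attention_weights(rng.standard_normal((5, 2, 6, 6)))[0]
        assert mask_loss(a, np.zeros((6, 6))) == pytest.approx(6.0, abs=1e-9)

    def test_matches_brute_force_sum(self, rng):
        a = masked_attention_weights(rng.standard_normal((4, 4)))[0]
        m = rng.uniform(0, 1, (4, 4))
        expected = sum(
            (1 - m[i, j]) * a[i, j] for i in range(4) for j in range(4)
        )
        assert mask_loss(a, m) == pytest.approx(expected, abs=1e-6)

    def test_bounds_given_stochastic_attention(self, rng):
        a = masked_attention_weights(rng.standard_normal((3, 2, 5, 5)))[0]
        m = rng.uniform(0, 1, (5, 5))
        assert 0.0 <= mask_loss(a, m) <= 5.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mask_loss(np.ones((2, 4, 4)) / 4, np.ones((3, 3)))


class TestSpatialAttention:
    def test_identical_summaries_give_uniform_weights(self):
        u = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        a_s, pooled = spatial_attention(u)
        np.testing.assert_allclose(a_s, 0.25, atol=1e-12)
        np.testing.assert_allclose(pooled, u[0], atol=1e-12)

    def test_single_channel(self):
        u = np.array([[3.0, -1.0]])
        a_s, pooled = spatial_attention(u)
        np.testing.assert_array_equal(a_s, [[1.0]])
        np.testing.assert_array_equal(pooled, u[0])

    def test_three_channel_hand_oracle(self, rng):
        u = rng.standard_normal((3, 4))
        a_s, pooled = spatial_attention(u)
        d = 4
        for i in range(3):
            e = [float(u[i] @ u[j]) / math.sqrt(d) for j in range(3)]
            soft = [math.exp(v) / sum(math.exp(w) for w in e) for v in e]
            np.testing.assert_allclose(a_s[i], soft, atol=1e-6)
        mixed = np.array([[sum(a_s[i, j] * u[j, k] for j in range(3)) for k in range(4)]
                          for i in range(3)])
        np.testing.assert_allclose(pooled, mixed.mean(axis=0), atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spatial_attention(np.empty((0, 4)))


class TestClassify:
    def test_equal_logits_give_uniform(self):
        probs = classify(np.zeros((2, 3)), np.zeros((3, 4)), np.zeros(4))
        np.testing.assert_allclose(probs, 0.25)

    def test_closed_form_two_class(self):
        w = np.array([[1.0, 0.0]])
        probs = classify(np.array([[10.0]]), w, np.zeros(2))
        assert probs[0, 0] == pytest.approx(1 / (1 + math.exp(-10)), rel=1e-12)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([[np.inf]]), np.ones((1, 2)), np.zeros(2))


class TestForward:
    def test_mask_identity_bitwise(self, rng):
        """An all-ones mask reproduces the mask-free network exactly."""
        cfg = tiny_config()
        model = EEGTransformer(cfg)
        frames = rng.standard_normal((3, 2, 4, 6))
        res_ones = model.forward(frames, mask_override=np.ones((4, 4)))
        model.config.use_adaptive_mask = False
        res_off = model.forward(frames)
        model.config.use_adaptive_mask = True
        assert np.array_equal(res_ones.probs, res_off.probs)
        assert res_ones.mask_loss == pytest.approx(0.0, abs=1e-12)

    def test_closed_mask_loss_equals_row_count(self, rng):
        cfg = tiny_config()
        model = EEGTransformer(cfg)
        frames = rng.standard_normal((2, 2, 4, 6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.forward(frames, mask_override=np.zeros((4, 4)))
        assert res.mask_loss == pytest.approx(cfg.seq_len, abs=1e-9)

    def test_deterministic_forward(self, rng):
        model = EEGTransformer(tiny_config())
        frames = rng.standard_normal((2, 2, 4, 6))
        r1 = model.forward(frames)
        r2 = model.forward(frames)
        assert np.array_equal(r1.probs, r2.probs)

    def test_embedding_linearity(self, rng):
        """Tokens minus bias and positional encoding scale linearly."""
        cfg = tiny_config(n_layers=0)
        model = EEGTransformer(cfg)
        w, b = model.params["embed.W"], model.params["embed.b"]
        frames = rng.standard_normal((1, 2, 4, 6))
        tok1 = frames @ w + b + model.pe
        tok2 = (2 * frames) @ w + b + model.pe
        np.testing.assert_allclose(tok2 - b - model.pe, 2 * (tok1 - b - model.pe), atol=1e-12)

    def test_zero_embedding_yields_positional_encoding(self, rng):
        cfg = tiny_config()
        model = EEGTransformer(cfg)
        model.params["embed.W"][:] = 0.0
        model.params["embed.b"][:] = 0.0
        frames = rng.standard_normal((1, 2, 4, 6))
        tok = frames @ model.params["embed.W"] + model.params["embed.b"] + model.pe
        np.testing.assert_array_equal(tok[0, 0], model.pe)

    def test_shape_mismatch_rejected(self, rng):
        model = EEGTransformer(tiny_config())
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((1, 2, 4, 5)))  # wrong frame dim
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((1, 3, 4, 6)))  # wrong channels

    def test_channel_permutation_leaves_pooled_output_invariant(self, rng):
        """With shared embeddings, permuting channels permutes the channel
        summaries and leaves the classifier input unchanged."""
        cfg = tiny_config(n_channels=3)
        model = EEGTransformer(cfg)
        frames = rng.standard_normal((2, 3, 4, 6))
        perm = np.array([2, 0, 1])
        res_a = model.forward(frames)
        res_b = model.forward(frames[:, perm])
        np.testing.assert_allclose(res_a.probs, res_b.probs, atol=1e-10)
        np.testing.assert_allclose(
            res_a.spatial[:, perm][:, :, perm], res_b.spatial, atol=1e-10
        )


class TestGradients:
    @staticmethod
    def finite_difference_check(model, frames, labels, h=1e-6, per_param=4):
        _, grads = model.loss_and_grads(frames, labels)
        worst = {}
        for name, w in model.params.items():
            flat = w.reshape(-1)
            stride = max(1, flat.size // per_param)
            for idx in range(0, flat.size, stride):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = model.loss(frames, labels)["total"]
                flat[idx] = orig - h
                lm = model.loss(frames, labels)["total"]
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[name].reshape(-1)[idx]
                diff = abs(numeric - analytic)
                if diff < 1e-7:  # below central-difference noise floor
                    continue
                denom = max(1e-8, abs(numeric) + abs(analytic))
                worst[name] = max(worst.get(name, 0.0), diff / denom)
        return worst

    def test_all_blocks_match_finite_differences(self, rng):
        model = EEGTransformer(tiny_config())
        frames = rng.standard_normal((3, 2, 4, 6))
        labels = np.array([0, 1, 1])
        worst = self.finite_difference_check(model, frames, labels)
        assert max(worst.values(), default=0.0) < 1e-4, worst

    def test_per_channel_embedding_gradients(self, rng):
        model = EEGTransformer(tiny_config(per_channel_embedding=True))
        frames = rng.standard_normal((2, 2, 4, 6))
        labels = np.array([0, 1])
        worst = self.finite_difference_check(model, frames, labels, per_param=3)
        assert max(worst.values(), default=0.0) < 1e-4, worst


def test_checkpoint_round_trip(tmp_path, rng):
    model = EEGTransformer(tiny_config())
    model.classes_ = ["alpha", "theta"]
    frames = rng.standard_normal((2, 2, 4, 6))
    before = model.forward(frames).probs
    model.save(tmp_path / "m.npz")
    loaded = EEGTransformer.load(tmp_path / "m.npz")
    assert loaded.classes_ == ["alpha", "theta"]
    assert loaded.config.to_dict() == model.config.to_dict()
    np.testing.assert_array_equal(loaded.forward(frames).probs, before)
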