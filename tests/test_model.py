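"""Layer-by-layer oracle checks for the network plus architecture wiring tests.

Every layer operation is recomputed by an independent, loop-based numpy
implementation on random small instances and must agree to 1e-5.
"""

import numpy as np
import pytest

import cannarel as cr
from cannarel.autodiff import Tensor
from cannarel.lexicon import Category
from cannarel.locator import EntitySpan, MaskedTweet
from cannarel.model import (
    AttentionParams,
    ClassifierParams,
    ContextEncoder,
    ContextEncoderSpec,
    FusionParams,
    RelationModel,
    VanillaAttentionParams,
    aggregate_vector,
    classify,
    conv_encode,
    cross_entropy,
    gated_fusion,
    position_aware_attention,
    vanilla_attention,
)
from cannarel.positions import EmbeddingTables

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------- oracles --


def oracle_conv(x, W, b, m):
    n, d = x.shape
    lpad = (m - 1) // 2
    xp = np.vstack([np.zeros((lpad, d)), x, np.zeros((m - 1 - lpad, d))])
    out = np.empty((n, W.shape[1]))
    for i in range(n):
        out[i] = np.tanh(xp[i : i + m].reshape(-1) @ W + b)
    return out


def oracle_pa_attention(h, q, Pc, Pd, Wh, Wq, Wc, Wd, v):
    n = h.shape[0]
    u = np.empty(n)
    for i in range(n):
        u[i] = v @ np.tanh(Wh @ h[i] + Wq @ q + Wc @ Pc[i] + Wd @ Pd[i])
    e = np.exp(u - u.max())
    alpha = e / e.sum()
    R = sum(alpha[j] * h[j] for j in range(n))
    return R, alpha


def oracle_vanilla(h, Wu, bu, v):
    n = h.shape[0]
    u = np.empty(n)
    for t in range(n):
        u[t] = np.tanh(Wu @ h[t] + bu) @ v
    e = np.exp(u - u.max())
    alpha = e / e.sum()
    return sum(alpha[j] * h[j] for j in range(n)), alpha


def oracle_fusion(R, B, WR, WB, Wg):
    hR = np.tanh(WR @ R)
    hB = np.tanh(WB @ B)
    g = 1 / (1 + np.exp(-(Wg @ np.concatenate([R, B]))))
    return g * hR + (1 - g) * hB


def oracle_softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def rand_attention(d_a, d_h, d_p):
    return AttentionParams(
        W_h=Tensor(RNG.standard_normal((d_a, d_h))),
        W_q=Tensor(RNG.standard_normal((d_a, d_h))),
        W_c=Tensor(RNG.standard_normal((d_a, d_p))),
        W_d=Tensor(RNG.standard_normal((d_a, d_p))),
        v=Tensor(RNG.standard_normal(d_a)),
    )


# ------------------------------------------------------------ layer tests --


class TestConvEncode:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_sliding_window_oracle(self, case):
        n = int(RNG.integers(1, 8))
        d = int(RNG.integers(2, 6))
        windows = [2, 3, 4]
        filters = [
            (m, Tensor(RNG.standard_normal((m * d, 3))), Tensor(RNG.standard_normal(3)))
            for m in windows
        ]
        x = Tensor(RNG.standard_normal((n, d)))
        got = conv_encode(x, filters)
        want = np.concatenate(
            [oracle_conv(x.data, W.data, b.data, m) for m, W, b in filters], axis=1
        )
        assert got.shape == (n, 9)
        np.testing.assert_allclose(got.data, want, atol=1e-5)

    def test_single_token_input_padded_to_length_one(self):
        d = 4
        filters = [
            (m, Tensor(RNG.standard_normal((m * d, 128))), Tensor(np.zeros(128)))
            for m in (2, 3, 4)
        ]
        out = conv_encode(Tensor(RNG.standard_normal((1, d))), filters)
        assert out.shape == (1, 384)

    def test_zero_input_zero_bias_is_fixed_point(self):
        d = 3
        filters = [(2, Tensor(RNG.standard_normal((2 * d, 5))), Tensor(np.zeros(5)))]
        out = conv_encode(Tensor(np.zeros((4, d))), filters)
        np.testing.assert_array_equal(out.data, np.zeros((4, 5)))


class TestAggregateVector:
    def test_identical_rows_give_that_row(self):
        v = RNG.standard_normal(5)
        q = aggregate_vector(Tensor(np.tile(v, (4, 1))))
        np.testing.assert_allclose(q.data, v)

    def test_opposite_rows_cancel(self):
        v = RNG.standard_normal(5)
        q = aggregate_vector(Tensor(np.stack([v, -v])))
        np.testing.assert_allclose(q.data, np.zeros(5), atol=1e-12)

    def test_matches_mean(self):
        h = RNG.standard_normal((7, 4))
        np.testing.assert_allclose(aggregate_vector(Tensor(h)).data, h.mean(axis=0))


class TestPositionAwareAttention:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_bruteforce_oracle(self, case):
        n, d_h, d_p, d_a = (int(RNG.integers(1, 8)) for _ in range(4))
        n = max(n, 1)
        h = Tensor(RNG.standard_normal((n, d_h)))
        q = aggregate_vector(h)
        Pc = Tensor(RNG.standard_normal((n, d_p)))
        Pd = Tensor(RNG.standard_normal((n, d_p)))
        p = rand_attention(d_a, d_h, d_p)
        R, alpha = position_aware_attention(h, q, Pc, Pd, p)
        Rw, aw = oracle_pa_attention(
            h.data, q.data, Pc.data, Pd.data, p.W_h.data, p.W_q.data, p.W_c.data, p.W_d.data, p.v.data
        )
        np.testing.assert_allclose(alpha.data, aw, atol=1e-5)
        np.testing.assert_allclose(R.data, Rw, atol=1e-5)

    def test_singleton_sequence(self):
        h = Tensor(RNG.standard_normal((1, 4)))
        p = rand_attention(3, 4, 2)
        R, alpha = position_aware_attention(h, aggregate_vector(h), Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2))), p)
        np.testing.assert_allclose(alpha.data, [1.0])
        np.testing.assert_allclose(R.data, h.data[0])

    def test_zero_context_vector_gives_uniform_weights_and_R_equals_q(self):
        n = 6
        h = Tensor(RNG.standard_normal((n, 5)))
        q = aggregate_vector(h)
        p = rand_attention(3, 5, 2)
        p.v = Tensor(np.zeros(3))
        R, alpha = position_aware_attention(h, q, Tensor(RNG.standard_normal((n, 2))), Tensor(RNG.standard_normal((n, 2))), p)
        np.testing.assert_allclose(alpha.data, np.full(n, 1 / n))
        np.testing.assert_allclose(R.data, q.data, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        h = Tensor(RNG.standard_normal((3, 5)))
        p = rand_attention(3, 4, 2)  # wrong d_h
        with pytest.raises(ValueError):
            position_aware_attention(h, aggregate_vector(h), Tensor(np.zeros((3, 2))), Tensor(np.zeros((3, 2))), p)


class TestVanillaAttention:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_bruteforce_oracle(self, case):
        n, d_h = int(RNG.integers(1, 8)), int(RNG.integers(2, 6))
        h = Tensor(RNG.standard_normal((n, d_h)))
        p = VanillaAttentionParams(
            W_u=Tensor(RNG.standard_normal((d_h, d_h))),
            b_u=Tensor(RNG.standard_normal(d_h)),
            v=Tensor(RNG.standard_normal(d_h)),
        )
        R, alpha = vanilla_attention(h, p)
        Rw, aw = oracle_vanilla(h.data, p.W_u.data, p.b_u.data, p.v.data)
        np.testing.assert_allclose(alpha.data, aw, atol=1e-5)
        np.testing.assert_allclose(R.data, Rw, atol=1e-5)

    def test_singleton_and_zero_vector_limits(self):
        h = Tensor(RNG.standard_normal((1, 3)))
        p = VanillaAttentionParams(Tensor(np.eye(3)), Tensor(np.zeros(3)), Tensor(np.ones(3)))
        _, alpha = vanilla_attention(h, p)
        np.testing.assert_allclose(alpha.data, [1.0])
        h = Tensor(RNG.standard_normal((5, 3)))
        p = VanillaAttentionParams(Tensor(np.eye(3)), Tensor(np.zeros(3)), Tensor(np.zeros(3)))
        _, alpha = vanilla_attention(h, p)
        np.testing.assert_allclose(alpha.data, np.full(5, 0.2))


class TestAttentionSimplexLaws:
    @pytest.mark.parametrize("kind", ["position", "vanilla"])
    def test_weights_nonnegative_and_sum_to_one(self, kind):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n, d_h = int(rng.integers(1, 9)), 4
            h = Tensor(rng.standard_normal((n, d_h)) * 3)
            if kind == "position":
                p = rand_attention(3, d_h, 2)
                _, alpha = position_aware_attention(
                    h, aggregate_vector(h), Tensor(rng.standard_normal((n, 2))),
                    Tensor(rng.standard_normal((n, 2))), p,
                )
            else:
                p = VanillaAttentionParams(
                    Tensor(rng.standard_normal((d_h, d_h))),
                    Tensor(rng.standard_normal(d_h)),
                    Tensor(rng.standard_normal(d_h)),
                )
                _, alpha = vanilla_attention(h, p)
            assert np.all(alpha.data >= 0)
            assert alpha.data.sum() == pytest.approx(1.0, abs=1e-9)


class TestGatedFusion:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_bruteforce_oracle(self, case):
        d_h, h_b, f = (int(RNG.integers(2, 6)) for _ in range(3))
        R, B = Tensor(RNG.standard_normal(d_h)), Tensor(RNG.standard_normal(h_b))
        p = FusionParams(
            W_R=Tensor(RNG.standard_normal((f, d_h))),
            W_B=Tensor(RNG.standard_normal((f, h_b))),
            W_g=Tensor(RNG.standard_normal((f, d_h + h_b))),
        )
        got = gated_fusion(R, B, p)
        want = oracle_fusion(R.data, B.data, p.W_R.data, p.W_B.data, p.W_g.data)
        np.testing.assert_allclose(got.data, want, atol=1e-5)

    def test_zero_gate_weights_average_the_branches(self):
        p = FusionParams(
            W_R=Tensor(RNG.standard_normal((4, 3))),
            W_B=Tensor(RNG.standard_normal((4, 5))),
            W_g=Tensor(np.zeros((4, 8))),
        )
        R, B = Tensor(RNG.standard_normal(3)), Tensor(RNG.standard_normal(5))
        fused = gated_fusion(R, B, p)
        want = 0.5 * np.tanh(p.W_R.data @ R.data) + 0.5 * np.tanh(p.W_B.data @ B.data)
        np.testing.assert_allclose(fused.data, want)

    def test_gate_saturation_recovers_single_branch(self):
        R, B = Tensor(np.array([1.0, -2.0])), Tensor(np.array([0.5]))
        p = FusionParams(
            W_R=Tensor(RNG.standard_normal((3, 2))),
            W_B=Tensor(RNG.standard_normal((3, 1))),
            W_g=Tensor(np.full((3, 3), 100.0)),  # strongly positive pre-activation
        )
        # make W_g.[R⊕B] large positive regardless of sign pattern
        p.W_g = Tensor(100.0 * np.sign(np.concatenate([R.data, B.data]))[None, :].repeat(3, 0))
        fused = gated_fusion(R, B, p)
        np.testing.assert_allclose(fused.data, np.tanh(p.W_R.data @ R.data), atol=1e-12)

    def test_gate_bounded_and_fused_between_branches(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            d_h, h_b, f = 3, 4, 5
            R, B = Tensor(rng.standard_normal(d_h) * 5), Tensor(rng.standard_normal(h_b) * 5)
            p = FusionParams(
                W_R=Tensor(rng.standard_normal((f, d_h)) * 3),
                W_B=Tensor(rng.standard_normal((f, h_b)) * 3),
                W_g=Tensor(rng.standard_normal((f, d_h + h_b)) * 3),
            )
            fused = gated_fusion(R, B, p).data
            hR = np.tanh(p.W_R.data @ R.data)
            hB = np.tanh(p.W_B.data @ B.data)
            lo, hi = np.minimum(hR, hB), np.maximum(hR, hB)
            assert np.all(fused >= lo - 1e-12) and np.all(fused <= hi + 1e-12)


class TestClassifier:
    def test_zero_weights_give_uniform(self):
        p = ClassifierParams(W=Tensor(np.zeros((4, 6))), a=Tensor(np.zeros(4)))
        probs = classify(Tensor(RNG.standard_normal(6)), p)
        np.testing.assert_allclose(probs.data, np.full(4, 0.25))

    def test_large_bias_dominates(self):
        p = ClassifierParams(W=Tensor(np.zeros((4, 2))), a=Tensor(np.array([50.0, 0, 0, 0])))
        probs = classify(Tensor(np.zeros(2)), p)
        assert probs.data[0] > 1 - 1e-12

    def test_normalization_and_oracle(self):
        for _ in range(20):
            p = ClassifierParams(
                W=Tensor(RNG.standard_normal((4, 5))), a=Tensor(RNG.standard_normal(4))
            )
            x = Tensor(RNG.standard_normal(5))
            probs = classify(x, p).data
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)
            np.testing.assert_allclose(probs, oracle_softmax(p.W.data @ x.data + p.a.data), atol=1e-5)

    def test_cross_entropy_matches_log_softmax(self):
        p = ClassifierParams(W=Tensor(RNG.standard_normal((4, 3))), a=Tensor(RNG.standard_normal(4)))
        x = Tensor(RNG.standard_normal(3))
        for y in range(4):
            loss = cross_entropy(x, p, y)
            probs = oracle_softmax(p.W.data @ x.data + p.a.data)
            assert float(loss.data) == pytest.approx(-np.log(probs[y]), abs=1e-9)


# ------------------------------------------------------- context encoder --


class TestContextEncoder:
    def test_representation_bitwise_stable(self):
        enc = ContextEncoder(ContextEncoderSpec.small(), seed=0)
        tokens = ["<cannabis>", "helps", "my", "<depression>"]
        a = enc.representation(tokens).data
        b = enc.representation(tokens).data
        np.testing.assert_array_equal(a, b)

    def test_layer_selection_changes_representation(self):
        spec_last = ContextEncoderSpec.small(layer_used=2)
        spec_second_last = ContextEncoderSpec.small(layer_used=1)
        enc_a = ContextEncoder(spec_last, seed=0)
        enc_b = ContextEncoder(spec_second_last, seed=0)
        tokens = ["weed", "and", "depression"]
        assert not np.allclose(enc_a.representation(tokens).data, enc_b.representation(tokens).data)

    def test_default_layer_is_second_last(self):
        assert ContextEncoderSpec.small().resolved_layer == 1
        assert ContextEncoderSpec().resolved_layer == 11

    def test_single_content_token_pooling_hand_trace(self):
        """With one content token, the pooled B is that token's row divided by 1."""
        enc = ContextEncoder(ContextEncoderSpec.small(), seed=3)
        states = enc.hidden_states(["weed"])
        layer = enc.spec.resolved_layer
        np.testing.assert_allclose(enc.representation(["weed"]).data, states[layer].data[1])

    def test_special_rows_do_not_contribute(self):
        spec = ContextEncoderSpec.small()
        enc = ContextEncoder(spec, seed=1)
        tokens = ["a", "b", "c"]
        states = enc.hidden_states(tokens)
        H = states[spec.resolved_layer].data
        np.testing.assert_allclose(enc.representation(tokens).data, H[1:-1].mean(axis=0), atol=1e-12)

    def test_cls_pooling_flag(self):
        spec = ContextEncoderSpec.small(pooling="cls")
        enc = ContextEncoder(spec, seed=1)
        tokens = ["a", "b"]
        H = enc.hidden_states(tokens)[spec.resolved_layer].data
        np.testing.assert_array_equal(enc.representation(tokens).data, H[0])

    def test_overlong_sequence_truncates_with_warning(self):
        spec = ContextEncoderSpec.small(max_len=8)
        enc = ContextEncoder(spec, seed=0)
        with pytest.warns(UserWarning, match="truncat"):
            B = enc.representation(["tok"] * 20)
        assert B.shape == (spec.hidden,)


# ----------------------------------------------------------- full network --


def _masked(tokens, c, d):
    return MaskedTweet(
        tuple(tokens),
        EntitySpan(c, c + 1, Category.CANNABIS, "<cannabis>"),
        EntitySpan(d, d + 1, Category.DEPRESSION, "<depression>"),
    )


@pytest.fixture(scope="module")
def toy_tables():
    vocab = ["i", "treat", "my", "with", "helps", "really", "flare", "lol"]
    return EmbeddingTables.random_init(vocab, word_dim=8, position_dim=4, clip=20, seed=0)


EXAMPLE = _masked(["i", "treat", "my", "<depression>", "with", "<cannabis>"], 5, 3)


class TestForward:
    @pytest.mark.parametrize("variant", cr.ARCH_VARIANTS)
    def test_all_variants_emit_probability_simplex(self, toy_tables, variant):
        model = RelationModel(toy_tables, cr.ModelConfig.small(variant=variant), seed=0)
        probs = model.forward(EXAMPLE).data
        assert probs.shape == (4,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_context_variant_has_no_encoder(self, toy_tables):
        model = RelationModel(toy_tables, cr.ModelConfig.small(variant="no_context"), seed=0)
        assert model.encoder is None

    def test_concat_fusion_classifier_width(self, toy_tables):
        cfg = cr.ModelConfig.small(variant="concat_fusion")
        model = RelationModel(toy_tables, cfg, seed=0)
        assert model.classifier.W.shape[1] == model.hidden_dim + cfg.encoder.hidden

    def test_gradient_reaches_mask_token_embedding(self, toy_tables):
        """Mask tokens are dedicated learned rows: the loss must propagate to them."""
        model = RelationModel(toy_tables, cr.ModelConfig.small(dropout=0.0), seed=0)
        loss = model.loss(EXAMPLE, "Reason", training=False)
        loss.backward()
        row = toy_tables.vocab["<cannabis>"]
        assert model.word_table.grad is not None
        assert np.abs(model.word_table.grad[row]).max() > 0

    def test_deterministic_eval_forward(self, toy_tables):
        m1 = RelationModel(toy_tables, cr.ModelConfig.small(), seed=7)
        m2 = RelationModel(toy_tables, cr.ModelConfig.small(), seed=7)
        np.testing.assert_array_equal(m1.forward(EXAMPLE).data, m2.forward(EXAMPLE).data)

    def test_permutation_covariance_of_attention_weights(self):
        """With window-1 convolution, permuting the token encodings together
        with their position embeddings permutes the attention weights
        identically (the aggregate vector is permutation-invariant)."""
        rng = np.random.default_rng(11)
        n, d, d_p = 6, 5, 3
        E = rng.standard_normal((n, d))
        Pc = rng.standard_normal((n, d_p))
        Pd = rng.standard_normal((n, d_p))
        filters = [(1, Tensor(rng.standard_normal((d + 2 * d_p, 7))), Tensor(rng.standard_normal(7)))]
        params = rand_attention(4, 7, d_p)

        def alpha_of(E_, Pc_, Pd_):
            x = Tensor(np.concatenate([E_, Pc_, Pd_], axis=1))
            h = conv_encode(x, filters)
            _, alpha = position_aware_attention(h, aggregate_vector(h), Tensor(Pc_), Tensor(Pd_), params)
            return alpha.data

        perm = rng.permutation(n)
        a = alpha_of(E, Pc, Pd)
        b = alpha_of(E[perm], Pc[perm], Pd[perm])
        np.testing.assert_allclose(a[perm], b, atol=1e-10)
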