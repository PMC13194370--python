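import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitlens.aggregator import (
    AggregatorConfig,
    RNNAggregator,
    attention_pool,
    build_variant,
    predict,
    run_rnn,
)
from traitlens.encoder import EmbeddingSequence


def embseq(vectors, n_pad=0, tid="t"):
    vectors = np.asarray(vectors, dtype=float)
    t, d = vectors.shape
    full = np.zeros((t + n_pad, d))
    full[:t] = vectors
    mask = np.zeros(t + n_pad, dtype=bool)
    mask[:t] = True
    return EmbeddingSequence(tid, full, mask)


class TestAttentionPool:
    def test_equal_logits_give_uniform_weights_and_mean_context(self):
        states = np.tile(np.array([0.7, -0.1, 0.4]), (4, 1))  # identical rows
        alpha, c = attention_pool(states, np.array([0.3, -0.2, 0.1]))
        assert np.allclose(alpha, 0.25)
        assert np.allclose(c, states.mean(axis=0))

    def test_single_window(self):
        h = np.array([[1.0, -2.0]])
        alpha, c = attention_pool(h, np.array([0.5, 0.5]))
        assert np.allclose(alpha, [1.0])
        assert np.allclose(c, h[0])

    def test_log_ratio_logits(self):
        # logits 0, ln2, ln4 -> weights 1/7, 2/7, 4/7
        states = np.array([[0.0], [np.log(2)], [np.log(4)]])
        alpha, _ = attention_pool(states, np.array([1.0]))
        assert np.allclose(alpha, [1 / 7, 2 / 7, 4 / 7])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(6, 4))
        w = rng.normal(size=4)
        alpha1, _ = attention_pool(states, w)
        shifted = states + np.linalg.lstsq(w[None], np.array([7.0]), rcond=None)[0]
        alpha2, _ = attention_pool(shifted, w)
        assert np.allclose(alpha1, alpha2, atol=1e-9)

    def test_pads_get_exact_zero(self):
        rng = np.random.default_rng(1)
        states = rng.normal(size=(5, 3))
        mask = np.array([True, False, True, True, False])
        alpha, c = attention_pool(states, rng.normal(size=3), mask)
        assert (alpha[~mask] == 0.0).all()
        assert abs(alpha.sum() - 1.0) < 1e-12

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            attention_pool(np.array([[np.inf]]), np.array([1.0]))

    @given(st.integers(1, 40), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_direct_exp_sum_oracle(self, t, seed):
        rng = np.random.default_rng(seed)
        states = rng.normal(0, 2, size=(t, 5))
        w = rng.normal(size=5)
        mask = rng.random(t) < 0.7
        if not mask.any():
            mask[0] = True
        alpha, c = attention_pool(states, w, mask)
        e = np.where(mask, np.exp(states @ w), 0.0)
        oracle = e / e.sum()
        assert np.abs(alpha - oracle).max() < 1e-10
        assert np.abs(c - oracle @ states).max() < 1e-10

    def test_context_containment(self):
        rng = np.random.default_rng(2)
        states = rng.normal(size=(7, 4))
        _, c = attention_pool(states, rng.normal(size=4))
        assert (c >= states.min(axis=0) - 1e-12).all()
        assert (c <= states.max(axis=0) + 1e-12).all()


def rnn_config(**kw):
    defaults = dict(variant="rnn", input_dim=4, hidden=3, layers=2, seed=5)
    defaults.update(kw)
    return AggregatorConfig(**defaults)


class TestRunRnn:
    def test_single_window_yields_single_state(self):
        model = build_variant(rnn_config())
        states = run_rnn(model, embseq(np.ones((1, 4)), n_pad=3))
        assert states.shape == (1, 3)

    def test_pad_rows_do_not_enter_recurrence(self):
        model = build_variant(rnn_config())
        rng = np.random.default_rng(3)
        vec = rng.normal(size=(3, 4))
        a = run_rnn(model, embseq(vec))
        b = run_rnn(model, embseq(vec, n_pad=5))
        assert np.allclose(a, b, atol=1e-14)

    def test_two_step_recurrence_matches_hand_oracle(self):
        """Step the published gate equations by hand for a 2-window input."""
        model = build_variant(rnn_config(layers=1, input_dim=2, hidden=3))
        layer = model.gru_layers[0]
        x = np.array([[0.5, -1.0], [2.0, 0.25]])

        def sig(v):
            return 1 / (1 + np.exp(-v))

        h = np.zeros(3)
        expected = []
        for t in range(2):
            gx = x[t] @ layer.w_ih.data + layer.b_ih.data
            gh = h @ layer.w_hh.data + layer.b_hh.data
            r = sig(gx[:3] + gh[:3])
            z = sig(gx[3:6] + gh[3:6])
            n = np.tanh(gx[6:] + r * gh[6:])
            h = (1 - z) * n + z * h
            expected.append(h.copy())
        states = run_rnn(model, embseq(x))
        assert np.allclose(states, np.array(expected), atol=1e-12)

    def test_all_pad_input_rejected(self):
        model = build_variant(rnn_config())
        seq = EmbeddingSequence("t", np.zeros((3, 4)), np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            run_rnn(model, seq)


class TestPredict:
    def test_zero_weight_head_returns_bias(self):
        model = build_variant(rnn_config())
        model.head.w.data[:] = 0.0
        model.head.b.data[:] = 1.25
        score, _ = predict(model, embseq(np.random.default_rng(0).normal(size=(3, 4))))
        assert score == pytest.approx(1.25)

    def test_pad_count_never_changes_score(self):
        rng = np.random.default_rng(4)
        vec = rng.normal(size=(4, 4))
        for variant in ("rnn", "ffn", "transformer"):
            model = build_variant(rnn_config(variant=variant, input_dim=4,
                                             tx_heads=2, tx_ffdim=8, dropout=0.1))
            s1, p1 = predict(model, embseq(vec))
            s2, p2 = predict(model, embseq(vec, n_pad=6))
            assert s1 == pytest.approx(s2, abs=1e-12)
            assert np.allclose(p1.alpha[:4], p2.alpha[:4], atol=1e-12)
            assert (p2.alpha[4:] == 0.0).all()

    def test_profile_satisfies_normalization_invariant(self):
        rng = np.random.default_rng(5)
        for variant in ("rnn", "ffn", "transformer"):
            model = build_variant(rnn_config(variant=variant, tx_heads=2, tx_ffdim=8))
            _, profile = predict(model, embseq(rng.normal(size=(5, 4)), n_pad=2))
            profile.validate()

    def test_dimension_mismatch_rejected(self):
        model = build_variant(rnn_config(input_dim=4))
        with pytest.raises(ValueError):
            predict(model, embseq(np.ones((2, 7))))


class TestBuildVariant:
    def test_rnn_default_shapes_follow_config(self):
        model = build_variant(AggregatorConfig(variant="rnn", input_dim=32))
        assert len(model.gru_layers) == 2
        assert model.gru_layers[0].w_ih.data.shape == (32, 768)  # 3 * 256
        assert model.gru_layers[1].w_hh.data.shape == (256, 768)
        assert model.w_attn.data.shape == (256, 1)

    def test_ffn_has_no_recurrent_or_attention_parameters(self):
        model = build_variant(rnn_config(variant="ffn", ffn_hidden=(6, 5)))
        names = [n for n, _ in model.named_parameters()]
        assert not any("gru" in n or "attn" in n for n in names)
        dims = [model.hidden_layers[0].w.data.shape, model.hidden_layers[1].w.data.shape]
        assert dims == [(4, 6), (6, 5)]

    def test_transformer_eval_mode_is_deterministic(self):
        model = build_variant(rnn_config(variant="transformer", tx_heads=2,
                                         tx_ffdim=8, dropout=0.5))
        seq = embseq(np.random.default_rng(6).normal(size=(4, 4)))
        s1, _ = predict(model, seq)
        s2, _ = predict(model, seq)
        assert s1 == s2

    def test_transformer_train_mode_applies_dropout(self):
        model = build_variant(rnn_config(variant="transformer", tx_heads=2,
                                         tx_ffdim=8, dropout=0.5))
        model.head.w.data[:] = 1.0  # zero-init head would mask the dropout
        model.train()
        x = np.random.default_rng(7).normal(size=(1, 4, 4))
        mask = np.ones((1, 4), dtype=bool)
        out1, _ = model.forward(x, mask)
        out2, _ = model.forward(x, mask)
        assert out1.data[0] != out2.data[0]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant(rnn_config(variant="lstm"))
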