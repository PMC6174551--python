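"""Equation-level oracles, gradient checks and training behavior.

The brute-force oracles below evaluate the GRU, attention and softmax
equations element by element with plain Python loops, independently of the
vectorized implementations they guard.
"""

import math

import numpy as np
import pytest

from chemrel.features import EncodedInstance
from chemrel.models import (
    AttentionParams,
    CNNParams,
    ClassifierParams,
    GRUParams,
    ModelConfig,
    RelationModel,
    TrainedModel,
    _pack,
    attention_pool,
    classify,
    cnn_encode,
    gru_forward,
    gru_step,
    predict,
    predict_label,
    train_model,
)


# ---------------------------------------------------------------------------
# brute-force oracles (loops + math.*, no numpy linear algebra)
# ---------------------------------------------------------------------------


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def _matvec(W, v):
    return [sum(W[i][j] * v[i] for i in range(len(v))) for j in range(len(W[0]))]


def oracle_gru_step(x, h_prev, p):
    D, H = len(x), len(h_prev)
    Wz, Wr, Wh = p.W_z.tolist(), p.W_r.tolist(), p.W_h.tolist()
    Uz, Ur, Uh = p.U_z.tolist(), p.U_r.tolist(), p.U_h.tolist()
    z = [_sig(a + b + c) for a, b, c in
         zip(_matvec(Wz, x), _matvec(Uz, h_prev), p.b_z)]
    r = [_sig(a + b + c) for a, b, c in
         zip(_matvec(Wr, x), _matvec(Ur, h_prev), p.b_r)]
    rh = [r[i] * h_prev[i] for i in range(H)]
    h_cand = [math.tanh(a + b + c) for a, b, c in
              zip(_matvec(Wh, x), _matvec(Uh, rh), p.b_h)]
    # the update gate scales the PREVIOUS state
    return [z[i] * h_prev[i] + (1 - z[i]) * h_cand[i] for i in range(H)]


def oracle_attention(hs, a):
    T, H = len(hs), len(hs[0])
    Ww, bw, uw = a.W_w.tolist(), a.b_w.tolist(), a.u_w.tolist()
    u = [[math.tanh(v + b) for v, b in zip(_matvec(Ww, h), bw)] for h in hs]
    scores = [sum(u[t][i] * uw[i] for i in range(H)) for t in range(T)]
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    alphas = [e / sum(exps) for e in exps]
    s = [sum(alphas[t] * hs[t][i] for t in range(T)) for i in range(H)]
    return alphas, s


def _random_gru(rng, D, H):
    return GRUParams(
        W_z=rng.normal(size=(D, H)), W_r=rng.normal(size=(D, H)),
        W_h=rng.normal(size=(D, H)), U_z=rng.normal(size=(H, H)),
        U_r=rng.normal(size=(H, H)), U_h=rng.normal(size=(H, H)),
        b_z=rng.normal(size=H), b_r=rng.normal(size=H), b_h=rng.normal(size=H),
    )


# ---------------------------------------------------------------------------


class TestGRUStep:
    def test_zero_params_halve_previous_state(self):
        H = 3
        p = GRUParams(*[np.zeros((2, H))] * 3, *[np.zeros((H, H))] * 3,
                      *[np.zeros(H)] * 3)
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(gru_step(np.zeros(2), v, p), 0.5 * v)

    def test_saturated_update_gate_keeps_previous_state(self):
        H = 2
        p = GRUParams(*[np.zeros((2, H))] * 3, *[np.zeros((H, H))] * 3,
                      np.full(H, 50.0), np.zeros(H), np.zeros(H))
        v = np.array([0.3, -0.7])
        np.testing.assert_allclose(gru_step(np.zeros(2), v, p), v, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            D, H = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = _random_gru(rng, D, H)
            x = rng.normal(size=D)
            h = rng.normal(size=H)
            expected = oracle_gru_step(list(x), list(h), p)
            np.testing.assert_allclose(gru_step(x, h, p), expected, atol=1e-6)

    def test_shape_mismatch_errors(self, rng):
        p = _random_gru(rng, 3, 2)
        with pytest.raises(ValueError):
            gru_step(np.zeros(4), np.zeros(2), p)


class TestGRUForward:
    def test_single_step_equals_step_from_zero(self, rng):
        p = _random_gru(rng, 3, 2)
        x = rng.normal(size=(1, 3))
        np.testing.assert_allclose(
            gru_forward(x, p)[0], gru_step(x[0], np.zeros(2), p)
        )

    def test_chained_steps(self, rng):
        p = _random_gru(rng, 3, 4)
        xs = rng.normal(size=(3, 3))
        hs = gru_forward(xs, p)
        h = np.zeros(4)
        for t in range(3):
            h = gru_step(xs[t], h, p)
            np.testing.assert_allclose(hs[t], h, atol=1e-10)

    def test_padding_content_ignored(self, rng):
        p = _random_gru(rng, 3, 2)
        xs1 = rng.normal(size=(5, 3))
        xs2 = xs1.copy()
        xs2[3:] = 99.0  # garbage in the padded tail
        h1 = gru_forward(xs1, p, true_length=3)
        h2 = gru_forward(xs2, p, true_length=3)
        np.testing.assert_array_equal(h1, h2)


class TestAttentionPool:
    def test_singleton_gets_weight_one(self, rng):
        a = AttentionParams.init(3, rng, np.float64)
        hs = rng.normal(size=(1, 3))
        alphas, s = attention_pool(hs, a)
        np.testing.assert_allclose(alphas, [1.0])
        np.testing.assert_allclose(s, hs[0])

    def test_identical_states_uniform_weights(self, rng):
        a = AttentionParams.init(3, rng, np.float64)
        hs = np.tile(rng.normal(size=3), (4, 1))
        alphas, _ = attention_pool(hs, a)
        np.testing.assert_allclose(alphas, np.full(4, 0.25), atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            H, T = int(rng.integers(1, 5)), int(rng.integers(1, 7))
            a = AttentionParams(
                W_w=rng.normal(size=(H, H)), b_w=rng.normal(size=H),
                u_w=rng.normal(size=H),
            )
            hs = rng.normal(size=(T, H))
            exp_alphas, exp_s = oracle_attention(hs.tolist(), a)
            alphas, s = attention_pool(hs, a)
            np.testing.assert_allclose(alphas, exp_alphas, atol=1e-6)
            np.testing.assert_allclose(s, exp_s, atol=1e-6)
            assert abs(alphas.sum() - 1.0) < 1e-6

    def test_empty_sequence_errors(self, rng):
        a = AttentionParams.init(2, rng, np.float64)
        with pytest.raises(ValueError):
            attention_pool(np.zeros((0, 2)), a)

    def test_padded_positions_excluded(self, rng):
        a = AttentionParams.init(3, rng, np.float64)
        hs = rng.normal(size=(5, 3))
        alphas, s = attention_pool(hs, a, true_length=3)
        assert np.all(alphas[3:] == 0.0)
        assert abs(alphas.sum() - 1.0) < 1e-9


class TestCNNEncode:
    def test_indicator_filter_fires_at_matching_window(self, rng):
        xs = np.zeros((5, 2))
        xs[2] = [1.0, -1.0]  # distinctive pattern at position 2
        W = np.zeros((3 * 2, 1))
        W[2] = 5.0  # responds to feature 0 of the window's middle token
        c = CNNParams(W=W, b=np.zeros(1), filter_length=3)
        # windows at 0..2; the one centered on position 2 is windows[1]
        acts = [math.tanh(5.0 * xs[p + 1, 0]) for p in range(3)]
        np.testing.assert_allclose(cnn_encode(xs, c), [max(acts)])

    def test_constant_input_all_windows_equal(self, rng):
        c = CNNParams.init(4, 7, 3, rng, np.float64)
        xs = np.ones((6, 4))
        out = cnn_encode(xs, c)
        expected = np.tanh(np.tile(xs[0], 3) @ c.W + c.b)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_output_width_equals_filter_count(self, rng):
        c = CNNParams.init(4, 100, 3, rng, np.float64)
        assert cnn_encode(np.zeros((10, 4)), c).shape == (100,)

    def test_short_sequence_errors(self, rng):
        c = CNNParams.init(4, 2, 3, rng, np.float64)
        with pytest.raises(ValueError):
            cnn_encode(np.zeros((2, 4)), c)


class TestClassifier:
    def test_zero_weights_uniform(self):
        cp = ClassifierParams(W=np.zeros((4, 6)), b=np.zeros(6))
        np.testing.assert_allclose(classify(np.ones(4), cp), np.full(6, 1 / 6))

    def test_simplex_property(self, rng):
        cp = ClassifierParams.init(5, rng, np.float64)
        probs = classify(rng.normal(size=5), cp)
        assert np.all(probs > 0) and np.all(probs < 1)
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_closed_form_softmax(self):
        cp = ClassifierParams(W=np.zeros((1, 6)), b=np.array([1.0, 0, 0, 0, 0, 0]))
        probs = classify(np.zeros(1), cp)
        denom = math.exp(1.0) + 5.0
        np.testing.assert_allclose(probs[0], math.exp(1.0) / denom, atol=1e-12)
        np.testing.assert_allclose(probs[1:], 1.0 / denom, atol=1e-12)

    @pytest.mark.parametrize(
        "probs, expected",
        [
            ([0.1, 0.5, 0.1, 0.1, 0.1, 0.1], 1),
            ([1 / 6] * 6, 0),  # tie -> lowest index
            ([0, 0, 0, 1, 0, 0], 3),
        ],
    )
    def test_predict_label(self, probs, expected):
        assert predict_label(np.array(probs)) == expected


# ---------------------------------------------------------------------------
# trainable models
# ---------------------------------------------------------------------------


def _toy_encoded(rng, n, T=7, V=15, n_classes=6, single_class=None):
    out = []
    for _ in range(n):
        L = int(rng.integers(3, T + 1))
        w = np.zeros(T, dtype=np.int64)
        w[:L] = rng.integers(2, V, L)
        pc = np.zeros(T, dtype=np.int64)
        pg = np.zeros(T, dtype=np.int64)
        pc[:L] = rng.integers(0, 20, L)
        pg[:L] = rng.integers(0, 20, L)
        y = single_class if single_class is not None else int(rng.integers(0, n_classes))
        # plant a class-specific token so the problem is learnable
        w[0] = 2 + y
        out.append(EncodedInstance(w, pc, pg, y, L, tokens=["t"] * L))
    return out


@pytest.mark.parametrize("kind", ["cnn", "gru", "att_gru"])
def test_analytic_gradients_match_finite_differences(kind, rng):
    cfg = ModelConfig(model=kind, rnn_dim=4, n_filters=3, filter_length=3,
                      dropout=0.0, dtype="float64", seed=2, pos_offset=10,
                      max_len=10)
    m = RelationModel(cfg, vocab_size=10, pos_table_size=20)
    insts = _toy_encoded(rng, 4, T=6, V=10)
    w, pc, pg, y, lens, mask = _pack(insts, min_len=3)
    _, _, cache = m.forward(w, pc, pg, lens, mask, train=False)
    grads = m.backward(cache, y)
    eps = 1e-6
    for name, p in m.params.items():
        flat_idx = rng.integers(0, p.size, size=min(3, p.size))
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            l1 = m.loss(m.forward(w, pc, pg, lens, mask, False)[0], y)
            p[idx] = orig - eps
            l2 = m.loss(m.forward(w, pc, pg, lens, mask, False)[0], y)
            p[idx] = orig
            num = (l1 - l2) / (2 * eps)
            ana = grads[name][idx]
            assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), (name, idx)


class TestTraining:
    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            train_model([], [], ModelConfig(), vocab_size=10)

    def test_single_class_collapse(self, rng):
        cfg = ModelConfig(model="gru", rnn_dim=8, epochs=3, seed=0,
                          pos_offset=10, max_len=8, batch_size=8)
        train = _toy_encoded(rng, 40, V=10, single_class=2)
        tm = train_model(train, train[:10], cfg, vocab_size=10)
        preds, _ = predict(tm.model, train[:10])
        assert np.all(preds == 2)

    def test_loss_decreases_on_learnable_toy(self, rng):
        cfg = ModelConfig(model="att_gru", rnn_dim=8, epochs=4, seed=1,
                          pos_offset=10, max_len=8, batch_size=16)
        train = _toy_encoded(rng, 120, V=12)
        tm = train_model(train, train[:20], cfg, vocab_size=12)
        losses = [h["train_loss"] for h in tm.history]
        assert losses[-1] < losses[0]
        assert isinstance(tm, TrainedModel) and tm.best_epoch >= 0

    def test_different_seeds_different_weights(self, rng):
        train = _toy_encoded(rng, 60, V=12)
        cfgs = [ModelConfig(model="cnn", n_filters=4, epochs=2, seed=s,
                            pos_offset=10, max_len=8, batch_size=16)
                for s in (0, 1)]
        m0 = train_model(train, train[:10], cfgs[0], vocab_size=12)
        m1 = train_model(train, train[:10], cfgs[1], vocab_size=12)
        assert not np.allclose(m0.model.params["W_f"], m1.model.params["W_f"])

    def test_inference_deterministic_and_alphas_simplex(self, rng):
        cfg = ModelConfig(model="att_gru", rnn_dim=6, epochs=1, seed=3,
                          pos_offset=10, max_len=8, batch_size=16)
        train = _toy_encoded(rng, 40, V=10)
        tm = train_model(train, train[:8], cfg, vocab_size=10)
        p1, a1 = predict(tm.model, train[:8])
        p2, a2 = predict(tm.model, train[:8])
        np.testing.assert_array_equal(p1, p2)
        for a, e in zip(a1, train[:8]):
            assert len(a) == e.true_length
            assert abs(a.sum() - 1.0) < 1e-5

    def test_cnn_returns_no_alphas(self, rng):
        cfg = ModelConfig(model="cnn", n_filters=4, epochs=1, seed=0,
                          pos_offset=10, max_len=8, batch_size=16)
        train = _toy_encoded(rng, 30, V=10)
        tm = train_model(train, train[:5], cfg, vocab_size=10)
        _, alphas = predict(tm.model, train[:5])
        assert alphas is None

    def test_unknown_model_kind_rejected(self):
        with pytest.raises(ValueError):
            RelationModel(ModelConfig(model="transformer"), 10, 20)
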