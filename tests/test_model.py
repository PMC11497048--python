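import numpy as np
import pytest

from utrlm import masking, model, tokenizer


@pytest.fixture(scope="module")
def vocab():
    return tokenizer.build_vocabulary(3)


@pytest.fixture(scope="module")
def toy_cfg(vocab):
    """d=4 toy for gradient checks (dropout off so losses are deterministic)."""
    return model.ModelConfig(
        vocab_size=len(vocab), n_layers=2, n_heads=2, d_model=4,
        d_ffn=8, max_positions=16, dropout=0.0,
    )


@pytest.fixture(scope="module")
def toy_setup(vocab, toy_cfg):
    params = model.init_params(toy_cfg, seed=0)
    w = tokenizer.encode_sequence("AUGACAUGGCAA", vocab, 16)
    plan = masking.plan_masking(w, vocab, mask_rate=0.3, seed=1)
    corr, tgt, lm = masking.apply_plan(w, plan, vocab)
    return params, w, corr, tgt, lm


class TestInit:
    def test_deterministic_given_seed(self, toy_cfg):
        p1 = model.init_params(toy_cfg, seed=3)
        p2 = model.init_params(toy_cfg, seed=3)
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_different_seeds_differ(self, toy_cfg):
        p1 = model.init_params(toy_cfg, seed=3)
        p2 = model.init_params(toy_cfg, seed=4)
        assert not np.array_equal(p1["tok_emb"], p2["tok_emb"])

    def test_shapes_match_config(self, toy_cfg):
        p = model.init_params(toy_cfg, seed=0)
        assert p["tok_emb"].shape == (toy_cfg.vocab_size, 4)
        assert p["pos_emb"].shape == (16, 4)
        assert p["L0.Wq"].shape == (4, 4)
        assert p["L0.W1"].shape == (4, 8)
        assert p["mlm_W"].shape == (4, toy_cfg.vocab_size)
        assert p["cls_W"].shape == (4, 2)

    def test_indivisible_heads_rejected(self, vocab):
        with pytest.raises(ValueError):
            model.ModelConfig(vocab_size=len(vocab), d_model=10, n_heads=3)


class TestEncoderContracts:
    def test_attention_rows_stochastic_every_layer(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        state = model.encode_window(params, toy_cfg, w)
        for A in state.attention:
            assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-5)

    def test_pad_keys_get_zero_attention(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        state = model.encode_window(params, toy_cfg, w)
        pad = w.ids == 0
        assert pad.any()
        for A in state.attention:
            assert np.allclose(A[:, :, pad], 0.0)

    def test_hand_computed_single_head_attention(self):
        """2-token toy, d=2, H=1: attention equals softmax(q.k / sqrt(d))."""
        cfg = model.ModelConfig(
            vocab_size=8, n_layers=1, n_heads=1, d_model=2, d_ffn=4,
            max_positions=4, dropout=0.0,
        )
        params = model.init_params(cfg, seed=0)
        params["tok_emb"] = np.array(
            [[0.0, 0], [0, 0], [1.0, 0], [0, 1.0], [0, 0], [0.5, 0.5],
             [0, 0], [0, 0]]
        )
        params["pos_emb"][:] = 0.0
        params["L0.Wq"] = np.array([[1.0, 0], [0, 1.0]])
        params["L0.Wk"] = np.array([[0, 1.0], [1.0, 0]])
        for nm in ("bq", "bk"):
            params[f"L0.{nm}"][:] = 0.0
        ids = np.array([[2, 3]])  # embeddings (1,0) and (0,1)
        _, attn, _ = model.forward(params, cfg, ids)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        Q = X @ params["L0.Wq"]
        K = X @ params["L0.Wk"]
        S = Q @ K.T / np.sqrt(2)
        expected = np.exp(S) / np.exp(S).sum(axis=1, keepdims=True)
        assert np.allclose(attn[0][0, 0], expected, atol=1e-12)

    def test_permutation_sensitivity(self, toy_setup, toy_cfg, vocab):
        """Positional embeddings make token order matter."""
        params, *_ = toy_setup
        w1 = tokenizer.encode_sequence("AUGACA", vocab, 16)
        w2 = tokenizer.encode_sequence("ACAAUG", vocab, 16)
        h1, _, _ = model.forward(params, toy_cfg, w1.ids[None])
        h2, _, _ = model.forward(params, toy_cfg, w2.ids[None])
        assert not np.allclose(h1[-1][0, 0], h2[-1][0, 0])


class TestGradients:
    def test_mlm_gradient_matches_numeric(self, toy_setup, toy_cfg):
        """Directional derivative vs analytic gradient to 1e-4 relative."""
        params, w, corr, tgt, lm = toy_setup
        _, grads = model.mlm_loss_and_grads(params, toy_cfg, corr, tgt, lm)
        rng = np.random.default_rng(7)
        eps = 1e-5
        for _ in range(3):
            u = {k: rng.normal(size=v.shape) for k, v in params.items()}
            for k in params:
                params[k] += eps * u[k]
            lp, _ = model.mlm_loss_and_grads(params, toy_cfg, corr, tgt, lm)
            for k in params:
                params[k] -= 2 * eps * u[k]
            lm_, _ = model.mlm_loss_and_grads(params, toy_cfg, corr, tgt, lm)
            for k in params:
                params[k] += eps * u[k]
            numeric = (lp - lm_) / (2 * eps)
            analytic = sum(float((grads[k] * u[k]).sum()) for k in params)
            assert abs(numeric - analytic) / abs(numeric) < 1e-4

    def test_classification_gradient_matches_numeric(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        ids = w.ids[None, :]
        labels = np.array([1])
        _, grads = model.classification_loss_and_grads(params, toy_cfg, ids, labels)
        rng = np.random.default_rng(11)
        eps = 1e-5
        u = {k: rng.normal(size=v.shape) for k, v in params.items()}
        for k in params:
            params[k] += eps * u[k]
        lp, _ = model.classification_loss_and_grads(params, toy_cfg, ids, labels)
        for k in params:
            params[k] -= 2 * eps * u[k]
        lm_, _ = model.classification_loss_and_grads(params, toy_cfg, ids, labels)
        for k in params:
            params[k] += eps * u[k]
        numeric = (lp - lm_) / (2 * eps)
        analytic = sum(float((grads[k] * u[k]).sum()) for k in params)
        assert abs(numeric - analytic) / abs(numeric) < 1e-4


class TestMlmLoss:
    def test_uniform_logits_give_log_vocab(self, toy_setup, toy_cfg):
        """Zeroed MLM head => uniform distribution => loss = ln 69 for k=3."""
        params, w, corr, tgt, lm = toy_setup
        p = {k: v.copy() for k, v in params.items()}
        p["mlm_W"][:] = 0.0
        p["mlm_b"][:] = 0.0
        loss = model.mlm_loss(p, toy_cfg, corr, tgt, lm)
        assert np.isclose(loss, np.log(69), atol=1e-12)

    def test_correct_one_hot_logits_drive_loss_to_zero(self, toy_cfg, vocab):
        """Saturating bias on the true class => loss -> 0."""
        params = model.init_params(toy_cfg, seed=0)
        w = tokenizer.encode_sequence("AUGACA", vocab, 16)
        tgt = w.ids.copy()
        lm = np.zeros_like(w.ids)
        lm[2] = 1
        p = {k: v.copy() for k, v in params.items()}
        p["mlm_W"][:] = 0.0
        p["mlm_b"][:] = -50.0
        p["mlm_b"][tgt[2]] = 50.0
        assert model.mlm_loss(p, toy_cfg, w.ids, tgt, lm) < 1e-8

    def test_hand_computed_four_class_softmax(self):
        """logits (1,0,0,0), target 0 => -ln(e/(e+3)) ~ 0.7437."""
        logits = np.array([1.0, 0.0, 0.0, 0.0])
        p = np.exp(logits) / np.exp(logits).sum()
        expected = -np.log(np.e / (np.e + 3))
        assert np.isclose(-np.log(p[0]), expected, atol=1e-10)
        assert np.isclose(expected, 0.7437, atol=5e-5)

    def test_empty_mask_warns_and_returns_zero(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        lm = np.zeros_like(w.ids)
        with pytest.warns(UserWarning):
            loss = model.mlm_loss(params, toy_cfg, w.ids, w.ids, lm)
        assert loss == 0.0


class TestHeads:
    def test_classification_probabilities_valid(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        p = model.classify_window(params, toy_cfg, w)
        assert 0.0 < p < 1.0

    def test_two_class_probs_sum_to_one(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        hidden, _, _ = model.forward(params, toy_cfg, w.ids[None])
        logits = hidden[-1][:, 0, :] @ params["cls_W"] + params["cls_b"]
        probs = np.exp(logits) / np.exp(logits).sum()
        assert np.isclose(probs.sum(), 1.0)

    def test_embed_single_window_equals_own_pool(self, toy_setup, toy_cfg):
        params, w, *_ = toy_setup
        emb = model.embed_long_sequence(params, toy_cfg, [w])
        hidden, _, _ = model.forward(params, toy_cfg, w.ids[None])
        pooled = hidden[-1][0, w.real_slice, :].mean(axis=0)
        assert np.allclose(emb, pooled)

    def test_embed_permutation_invariant_across_windows(self, toy_setup, toy_cfg, vocab):
        params, *_ = toy_setup
        ws = [
            tokenizer.encode_sequence(s, vocab, 16)
            for s in ("AUGACA", "GGCCAA", "UUUGGG")
        ]
        e1 = model.embed_long_sequence(params, toy_cfg, ws)
        e2 = model.embed_long_sequence(params, toy_cfg, ws[::-1])
        assert np.allclose(e1, e2)

    def test_multilabel_head_outputs_independent_sigmoids(self):
        head = model.MultiLabelHead(d=8, n_labels=6, seed=0)
        X = np.random.default_rng(0).normal(size=(5, 8))
        P = head.predict_proba(X)
        assert P.shape == (5, 6)
        assert ((P > 0) & (P < 1)).all()
        # no sum-to-1 constraint across labels
        assert not np.allclose(P.sum(axis=1), 1.0)

    def test_multilabel_head_fits_separable_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 8))
        W = rng.normal(size=(8, 6))
        Y = ((X @ W) > 0).astype(int)
        head = model.MultiLabelHead(d=8, n_labels=6, seed=0)
        head.fit(X, Y, n_iter=800)
        acc = (head.predict(X) == Y).mean()
        assert acc > 0.95


class TestCheckpoint:
    def test_round_trip(self, toy_setup, toy_cfg, tmp_path):
        params, *_ = toy_setup
        model.save_checkpoint(tmp_path / "ckpt", params, toy_cfg)
        back, cfg = model.load_checkpoint(tmp_path / "ckpt")
        assert cfg == toy_cfg
        assert all(np.array_equal(back[k], params[k]) for k in params)
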