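import numpy as np
import pytest

from utrlm import attention, model, tokenizer
from utrlm.attention import cls_attention, token_to_nucleotide


@pytest.fixture(scope="module")
def vocab():
    return tokenizer.build_vocabulary(3)


@pytest.fixture(scope="module")
def setup(vocab):
    cfg = model.ModelConfig.tiny(vocab_size=len(vocab), max_positions=32)
    params = model.init_params(cfg, seed=0)
    w = tokenizer.encode_sequence("AUGACAUGGCAAUGC", vocab, 32)
    state = model.encode_window(params, cfg, w)
    return params, cfg, w, state


class TestClsAttention:
    def test_scores_sum_to_n_heads(self, setup):
        _, cfg, w, state = setup
        for layer in range(cfg.n_layers):
            alpha = cls_attention(state, layer=layer)
            assert alpha.shape == (w.n_real_tokens,)
            assert np.isclose(alpha.sum(), cfg.n_heads, atol=1e-5)
            assert (alpha >= 0).all()

    def test_uniform_attention_gives_h_over_j(self, setup):
        """Hand-built uniform maps: every token receives H/J."""
        _, cfg, w, state = setup
        J = w.n_real_tokens
        T = w.ids.shape[0]
        uniform = np.zeros((cfg.n_heads, T, T))
        real = slice(1, 1 + J)
        uniform[:, :, real] = 1.0 / J
        st2 = model.EncoderState(
            hidden=state.hidden, attention=[uniform], n_real_tokens=J, ids=w.ids
        )
        alpha = cls_attention(st2, layer=0)
        assert np.allclose(alpha, cfg.n_heads / J)

    def test_hand_computed_two_token_case(self):
        """One head, hand-set q* and keys: alpha = softmax(q*.k / sqrt(d))."""
        q = np.array([1.0, 0.5])
        k1 = np.array([0.2, -0.3])
        k2 = np.array([-1.0, 0.8])
        scale = np.sqrt(2)
        logits = np.array([q @ k1, q @ k2]) / scale
        expected = np.exp(logits) / np.exp(logits).sum()
        # package the same numbers as an attention map ([CLS], t1, t2, [SEP])
        row = np.zeros(4)
        row[1:3] = expected
        A = np.zeros((1, 4, 4))
        A[0, 0] = row
        st = model.EncoderState(
            hidden=[], attention=[A], n_real_tokens=2,
            ids=np.array([2, 5, 6, 3]),
        )
        alpha = cls_attention(st, layer=0)
        assert np.allclose(alpha, expected, atol=1e-6)

    def test_layer_out_of_range(self, setup):
        *_, state = setup
        with pytest.raises(IndexError):
            cls_attention(state, layer=5)


class TestTokenToNucleotide:
    def test_first_nucleotide_single_cover(self):
        tok = np.array([1.0, 2.0, 3.0, 4.0])
        nt = token_to_nucleotide(tok, k=3, L=6)
        assert nt[0] == 1.0

    def test_interior_mean_of_three(self):
        tok = np.array([1.0, 2.0, 3.0, 4.0])
        nt = token_to_nucleotide(tok, k=3, L=6)
        assert nt[2] == pytest.approx((1 + 2 + 3) / 3)
        assert nt[3] == pytest.approx((2 + 3 + 4) / 3)

    def test_constant_scores_stay_constant(self):
        nt = token_to_nucleotide(np.full(10, 0.7), k=3, L=12)
        assert np.allclose(nt, 0.7)

    def test_interior_total_preserved(self):
        """For L >> k, total nucleotide score ~ total token score (edges O(k))."""
        rng = np.random.default_rng(0)
        tok = rng.random(498)
        nt = token_to_nucleotide(tok, k=3, L=500)
        assert abs(nt.sum() - tok.sum()) < 3 * tok.max() * 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            token_to_nucleotide(np.ones(5), k=3, L=6)


class TestLandscape:
    def test_identical_windows_equal_single_profile(self, setup, vocab):
        params, cfg, w, _ = setup
        prof = attention.attention_profile(params, cfg, w, vocab.k)
        land = attention.attention_landscape(params, cfg, [w, w, w], [1, 1, 1], vocab.k)
        assert np.allclose(land[1], prof.nucleotide_scores)

    def test_planted_signal_peaks_in_motif_span(self, study_result):
        """On fixed-position planted windows, the positive-class landscape
        peaks inside the planted span while negatives stay flatter."""
        from utrlm import synthetic

        r = study_result
        spec = synthetic.GeneratorSpec(
            n_sequences=60, length=100, motif=r.planted_motif,
            plant_rate=1.0, plant_position="fixed:45", seed=11,
        )
        rng = np.random.default_rng(11)
        pos_recs, _ = synthetic.plant_motif(
            synthetic.generate_background(spec, rng), spec, rng
        )
        neg_recs = synthetic.generate_background(
            synthetic.GeneratorSpec(n_sequences=60, length=100, seed=12)
        )
        windows, labels = [], []
        for recs, lab in ((pos_recs, 1), (neg_recs, 0)):
            for rec in recs:
                windows.append(
                    tokenizer.encode_sequence(rec.sequence, r.vocab, r.config.max_positions)
                )
                labels.append(lab)
        land = attention.attention_landscape(
            r.params, r.config, windows, labels, r.vocab.k
        )
        span = range(45, 45 + len(r.planted_motif))
        assert land[1].argmax() in span
        pos_peak = land[1].max() / land[1].mean()
        neg_peak = land[0].max() / land[0].mean()
        assert pos_peak > neg_peak


class TestMutationMap:
    def test_shape_and_reference_zeros(self, setup, vocab):
        params, cfg, *_ = setup
        seq = "AUGACAUGGC"
        mm = attention.mutation_map(params, cfg, seq, vocab)
        assert mm.delta.shape == (len(seq), 4)
        for i, base in enumerate(seq):
            assert mm.delta[i, "ACGU".index(base)] == 0.0

    def test_deltas_bounded_by_probability_range(self, setup, vocab):
        params, cfg, *_ = setup
        mm = attention.mutation_map(params, cfg, "AUGACAUGGC", vocab)
        assert (mm.delta >= -1.0).all() and (mm.delta <= 1.0).all()
        assert 0.0 < mm.wildtype_score < 1.0

    def test_n_rejected(self, setup, vocab):
        params, cfg, *_ = setup
        with pytest.raises(ValueError):
            attention.mutation_map(params, cfg, "AUGNCA", vocab)

    def test_disrupting_planted_consensus_lowers_score(self, study_result):
        """Mutating inside the planted motif of a confident positive window
        drops the fine-tuned classifier's probability."""
        r = study_result
        positive = next(
            it for it in r.splits.test
            if it.label == 1 and it.ground_truth is not None
        )
        mm = attention.mutation_map(r.params, r.config, positive.sequence, r.vocab)
        iv = positive.ground_truth
        motif_deltas = mm.delta[iv.start : iv.end]
        assert motif_deltas.min() < -0.2
        assert motif_deltas.sum() < 0

    def test_padding_invariance(self, setup, vocab):
        """Scores do not depend on how much [PAD] follows the window."""
        params, cfg, *_ = setup
        seq = "AUGACAUGGC"
        w1 = tokenizer.encode_sequence(seq, vocab, 16)
        w2 = tokenizer.encode_sequence(seq, vocab, 32)
        p1 = model.classify_window(params, cfg, w1)
        p2 = model.classify_window(params, cfg, w2)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestTrackIO:
    def test_nucleotide_track_tsv(self, setup, vocab, tmp_path):
        params, cfg, w, _ = setup
        prof = attention.attention_profile(params, cfg, w, vocab.k)
        path = tmp_path / "track.tsv"
        attention.write_nucleotide_track(prof, "seq1", path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(prof.nucleotide_scores)
        seq_id, start, end, score = lines[0].split("\t")
        assert (seq_id, start, end) == ("seq1", "0", "1")
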