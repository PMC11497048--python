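"""The end-to-end planted-motif study at desk scale.

One function wires the whole toolkit together on synthetic data with
known ground truth: generate a pre-training corpus and an RBP-style
window dataset, pre-train the tiny encoder with span masking, fine-tune
from the pre-trained and from a random initialization, score the held-out
test split, and run attention-guided motif discovery on the training
positives. This is the package's reference experiment: if the planted
consensus comes back out of the attention maps, every stage in between
is doing its job.

Default study conditions: 200 pre-training sequences of 120 nt, 300
pre-training steps, 150 positive / 300 negative 100-nt fine-tuning
windows with a UGUAUAU consensus planted in 90% of positives, k = 6
tokens, and the tiny 2-layer / 2-head / d = 32 encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import attention, evaluation, masking, model, motifs, synthetic, tokenizer, training


@dataclass
class StudyResult:
    pretrained_report: evaluation.MetricReport
    scratch_report: evaluation.MetricReport
    mlm_initial_loss: float
    mlm_final_loss: float
    masked_recovery_acc: float
    consensus: str | None
    hamming_to_planted: int | None
    n_significant: int
    planted_motif: str
    params: dict
    config: model.ModelConfig
    vocab: tokenizer.Vocabulary
    splits: synthetic.DatasetSplits


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def discover_motifs(
    params: dict,
    config: model.ModelConfig,
    vocab: tokenizer.Vocabulary,
    positives: list[str],
    negatives: list[str],
    alpha: float = motifs.DEFAULT_ALPHA,
) -> tuple[list[motifs.MotifCandidate], list[motifs.MotifCluster]]:
    """High-attention 7-mer enrichment of positives against negatives."""
    regions = []
    for seq in positives:
        w = tokenizer.encode_sequence(seq, vocab, config.max_positions)
        prof = attention.attention_profile(params, config, w, vocab.k)
        regions.append(motifs.high_attention_regions(prof))
    cands = motifs.count_candidates(regions, positives, negatives)
    cands = motifs.score_candidates(
        cands, n_fg=len(positives), n_total=len(positives) + len(negatives),
        alpha=alpha,
    )
    clusters = motifs.merge_candidates([c for c in cands if c.significant])
    return cands, clusters


def planted_motif_study(
    seed: int,
    k: int = 6,
    n_corpus: int = 200,
    corpus_length: int = 120,
    pretrain_steps: int = 300,
    n_pos: int = 150,
    planted_motif: str = "UGUAUAU",
    plant_rate: float = 0.9,
    max_positions: int = 128,
    finetune_epochs: int = 12,
    pretrain_lr: float = 5e-3,
    finetune_lr: float = 2e-3,
) -> StudyResult:
    """Run the full scaled-down pipeline; deterministic given seed."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4) % (2**31)]
    vocab = tokenizer.build_vocabulary(k)
    config = model.ModelConfig.tiny(vocab_size=len(vocab), max_positions=max_positions)

    # --- pre-training on the synthetic 3'UTR-like corpus
    _, corpus = synthetic.make_pretrain_corpus(
        n_sequences=n_corpus, length=corpus_length, vocab=vocab,
        max_positions=max_positions, seed=seeds[0],
    )
    sched = training.Schedule(
        peak_lr=pretrain_lr, warmup_steps=max(1, pretrain_steps // 10),
        total_steps=pretrain_steps,
    )
    pre_params, history = training.pretrain(
        corpus, vocab, config, sched, training.OptimSpec(clip_norm=5.0),
        seed=seeds[1], batch_size=32,
    )
    mlm_initial = history[0]["loss"]
    mlm_final = float(np.mean([h["loss"] for h in history[-20:]]))

    # masked-token recovery on a held-out style probe
    rng = np.random.default_rng(seeds[1])
    hits = total = 0
    for w in corpus[:20]:
        plan = masking.plan_masking(w, vocab, mask_rate=0.15, rng=rng)
        corr, tgt, lm = masking.apply_plan(w, plan, vocab)
        pred = model.mlm_predict(pre_params, config, corr)[0]
        m = lm.astype(bool)
        hits += int((pred[m] == tgt[m]).sum())
        total += int(m.sum())
    recovery = hits / max(total, 1)

    # --- fine-tuning on the planted-motif window dataset
    splits = synthetic.make_rbp_dataset(
        n_pos=n_pos, motif=planted_motif, plant_rate=plant_rate, seed=seeds[2]
    )
    train_tok = synthetic.windows_to_tokenized(splits.train, vocab, max_positions)
    val_tok = synthetic.windows_to_tokenized(splits.val, vocab, max_positions)
    test_tok = synthetic.windows_to_tokenized(splits.test, vocab, max_positions)
    n_steps = finetune_epochs * int(np.ceil(len(train_tok) / 16))
    fsched = training.Schedule(
        peak_lr=finetune_lr, warmup_steps=max(1, n_steps // 10), total_steps=n_steps
    )
    test_ids = np.stack([w.ids for w, _ in test_tok])
    test_labels = np.array([lab for _, lab in test_tok])

    ft_params, _ = training.finetune(
        pre_params, config, train_tok, fsched, training.OptimSpec(),
        seed=seeds[3], epochs=finetune_epochs, val_set=val_tok,
    )
    pretrained_report = evaluation.compute_metrics(
        model.classify_batch(ft_params, config, test_ids), test_labels
    )
    scratch_init = model.init_params(config, seed=seeds[3])
    sc_params, _ = training.finetune(
        scratch_init, config, train_tok, fsched, training.OptimSpec(),
        seed=seeds[3], epochs=finetune_epochs, val_set=val_tok,
    )
    scratch_report = evaluation.compute_metrics(
        model.classify_batch(sc_params, config, test_ids), test_labels
    )

    # --- motif discovery on the training positives
    positives = [it.sequence for it in splits.train if it.label == 1]
    negatives = [it.sequence for it in splits.train if it.label == 0]
    cands, clusters = discover_motifs(ft_params, config, vocab, positives, negatives)
    n_sig = sum(c.significant for c in cands)
    consensus = ham = None
    if clusters:
        pwm = motifs.build_pwm(clusters[0])
        consensus = pwm.consensus
        ham = hamming(consensus, planted_motif)

    return StudyResult(
        pretrained_report=pretrained_report,
        scratch_report=scratch_report,
        mlm_initial_loss=float(mlm_initial),
        mlm_final_loss=mlm_final,
        masked_recovery_acc=float(recovery),
        consensus=consensus,
        hamming_to_planted=ham,
        n_significant=n_sig,
        planted_motif=planted_motif,
        params=ft_params,
        config=config,
        vocab=vocab,
        splits=splits,
    )
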