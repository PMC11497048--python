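# utrlm

Masked language modelling and attention-based regulatory-motif discovery
for 3' untranslated regions (3'UTRs) of mRNAs.

3'UTRs carry the cis-regulatory elements — RNA-binding-protein (RBP)
binding sites, m6A modification contexts, localization zipcodes — that
govern post-transcriptional regulation. `utrlm` treats 3'UTR sequence as
language: it tokenizes RNA into overlapping k-mers, pre-trains a
BERT-style bidirectional encoder with a span-masked language-model
objective, fine-tunes it on window-classification tasks (RBP binding,
m6A sites) or frozen-embedding multi-label tasks (subcellular
localization), and then reads regulatory motifs back out of the model's
own attention via hypergeometric enrichment. A synthetic planted-motif
generator makes the entire pipeline trainable and testable on one CPU
in minutes, with full ground truth.

The package is for computational biologists who want an inspectable,
pure-NumPy implementation of this modelling stack at configurable scale
— every gradient is hand-derived and verified against finite
differences in the test suite.

## The model

Sequences are tokenized into stride-1 k-mers ("AUGACA" → AUG, UGA, GAC,
ACA at k = 3), framed as `[CLS] t1 … tn [SEP]` over a vocabulary of
4^k + 5 tokens, and encoded by a stack of post-norm transformer blocks
(multi-head scaled dot-product attention, GeLU feed-forward, learned
positional embeddings). Pre-training masks 15% of tokens in contiguous
k-length spans — because stride-1 k-mers overlap, span masking is what
prevents a masked token from being read off its neighbours — with the
80/10/10 [MASK]/random/keep corruption scheme, optimized by AdamW
(β₁ 0.9, β₂ 0.98, ε 1e-6, weight decay 0.01) under a linear
warmup–decay schedule.

For interpretation, the importance of token j is its [CLS]-query
attention summed over heads, α_j = Σ_h softmax_j(q*ᵀk_j/√d_h),
converted to per-nucleotide tracks by averaging the covering k-mers.
High-attention regions of positive sequences are scanned for 7-mer
candidates, tested for over-representation against the negative set
with a one-sided hypergeometric tail, Benjamini–Hochberg corrected
(significant at adjusted p < 0.005), merged by approximate alignment,
and rendered as position weight matrices (MEME minimal export).
Saturation mutagenesis maps score every substitution as
P(mutant) − P(wild-type) under a fine-tuned classifier.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

The reference experiment generates everything it needs and runs in
about two minutes on one CPU:

```python
from utrlm.pipeline import planted_motif_study

r = planted_motif_study(seed=1)
print(f"held-out AUROC (pre-trained init): {r.pretrained_report.auroc:.3f}")
print(f"held-out AUROC (scratch init):     {r.scratch_report.auroc:.3f}")
print(f"MLM loss: {r.mlm_initial_loss:.2f} -> {r.mlm_final_loss:.2f}")
print(f"significant 7-mers: {r.n_significant}; "
      f"top consensus {r.consensus} (Hamming {r.hamming_to_planted} to planted)")
```

prints

```
held-out AUROC (pre-trained init): 0.934
held-out AUROC (scratch init):     0.847
MLM loss: 8.32 -> 6.74
significant 7-mers: 1; top consensus UGUAUAU (Hamming 0 to planted)
```

Reading: a tiny encoder (2 layers, 2 heads, d = 32, k = 6) was
pre-trained for 300 steps on a 200-sequence synthetic corpus, then
fine-tuned on 150 positive / 300 negative 100-nt windows in which the
PUM2-like consensus UGUAUAU was planted in 90% of positives. Starting
from the pre-trained state beats random initialization on held-out
windows (0.934 vs 0.847; the 0.9 plant rate caps attainable AUROC near
0.95), the masking objective is being learned (loss drops from the
uniform ~ln 4101 ≈ 8.3), and attention-guided enrichment recovers the
planted motif exactly as the only significant candidate.

The same flow is available from the shell:

```bash
utrlm synth --task rbp --n-pos 50 --seed 1 --out data/
utrlm pretrain --corpus corpus.fasta --k 6 --steps 300 --out ckpt/
utrlm finetune --checkpoint ckpt/ --train data/train.tsv --val data/val.tsv --out ft/
utrlm predict  --checkpoint ft/ --data data/test.tsv --out preds.tsv
utrlm motifs   --checkpoint ft/ --data data/train.tsv --out motifs/
utrlm mutmap   --checkpoint ft/ --sequence ACGUACGUUGUAUAUACG --out mm.tsv
```

## Layout

| module | role |
| --- | --- |
| `utrlm.seq_io` | FASTA/BED/TSV I/O, windowing, redundancy filter |
| `utrlm.tokenizer` | k-mer vocabulary, encode/decode, special tokens |
| `utrlm.masking` | span-contiguous MLM masking plans |
| `utrlm.model` | NumPy transformer encoder, losses, task heads |
| `utrlm.training` | AdamW, warmup–decay schedule, pre-train/fine-tune loops |
| `utrlm.attention` | α scores, nucleotide tracks, landscapes, mutation maps |
| `utrlm.motifs` | high-attention regions, hypergeometric + BH, PWM, MEME |
| `utrlm.evaluation` | AUROC/AUPRC/F1/MCC/ACC, positional enrichment, CV |
| `utrlm.synthetic` | planted-motif generators for all task geometries |
| `utrlm.pipeline` | the end-to-end desk-scale study |
| `utrlm.cli` | `utrlm` command-line interface |
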