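# Methods

`utrlm` models 3'UTR sequence as language: overlapping k-mer tokens, a
BERT-style bidirectional encoder pre-trained with a masked-language-model
(MLM) objective, task heads fine-tuned on labeled windows, and motif
read-out from the encoder's own attention. This note records the model,
the numerical choices, what the synthetic data does and does not emulate,
and the design decisions taken where more than one reading was possible.

## Tokenization

A sequence over {A, C, G, U} is tokenized into overlapping k-mers at
stride 1 (k configurable in [3, 6]), so a length-L sequence yields
L − k + 1 tokens and each nucleotide is covered by up to k tokens. The
vocabulary holds all 4^k k-mers plus five special tokens — [PAD], [UNK],
[CLS], [SEP], [MASK] — for a total of 4^k + 5. Specials take ids 0–4
([PAD] = 0 so padded id arrays are zero-filled); k-mers follow in
lexicographic A < C < G < U order, giving stable ids across runs. Any
k-mer touching an ambiguous base (N) becomes [UNK]. DNA input is
normalized on read (T → U, uppercase).

Windows longer than the model's position budget are split into
non-overlapping fragments left to right. The final short fragment is
*not* padded at the sequence level; it is padded with [PAD] ids after
tokenization, at the model boundary where [PAD] exists. Sequence files
therefore stay faithful to their input.

## Encoder

The encoder is the standard post-norm transformer:
embeddings = token embedding + learned absolute positional embedding;
each of n_layers blocks applies multi-head scaled dot-product
self-attention (per-head scale √d_h, d_h = d/H), a residual connection
and LayerNorm, then a position-wise FFN (single hidden layer of width
d_ffn with GeLU) with residual and LayerNorm. [PAD] key positions are
masked to −∞ before every softmax, so padding receives exactly zero
attention and attention rows are stochastic over real positions. The
reference configuration is 12 layers, 12 heads, d = 768, FFN 3072,
512 positions; desk-scale work uses `ModelConfig.tiny` (2 layers,
2 heads, d = 32, FFN 64, 128 positions).

The implementation is pure NumPy (float64) with a hand-derived backward
pass for every block. Correctness is enforced by a directional-derivative
check in the test suite: numeric and analytic gradients of the MLM and
classification losses agree to better than 1e-4 relative on a d = 4 toy.
Dropout (default 0.1) uses inverted scaling and is applied to the
embedding output and both sublayer outputs, in pre-training and
fine-tuning alike; it is disabled outside training mode so all
evaluation-time outputs are deterministic.

## Masking objective

15% of a window's real tokens are masked per step. Because stride-1
k-mers overlap, independently masked tokens could be read off their
unmasked neighbours; masking therefore proceeds in contiguous spans:
an anchor token expands to the k token positions starting at the anchor
(the tokens whose windows overlap the anchor's nucleotides), clipped at
the window end and truncated once the budget round(0.15 · n) is met.
Overlapping spans merge. Per masked token the corruption is 80% [MASK],
10% a random k-mer token (never a special), 10% unchanged — drawn at the
token level, since the replacement fractions are defined per token.
[UNK] tokens and specials are never masked. Masks are re-sampled every
step (dynamic masking). The loss is the mean cross-entropy of the true
token over masked positions only; an empty mask defines the loss as 0
with a warning.

## Optimization

AdamW with β₁ = 0.9, β₂ = 0.98, ε = 1e-6 and decoupled weight decay 0.01
applied to matrices and embeddings (not biases or LayerNorm parameters),
under a linear warmup / linear decay schedule and global-norm gradient
clipping. The full-scale reference schedule is 0 → 4e-4 over 10k steps,
decaying to 0 at 200k, with fine-tuning peaking at 5e-5; those remain
the defaults of `Schedule` and the CLI at full scale. The tiny desk
configuration needs larger steps to move at all in a few hundred
updates: pre-training uses peak 5e-3 with clip norm 5 and batch 32;
fine-tuning uses peak 2e-3, clip norm 1, batch 16. Binary fine-tuning
updates the whole network from the chosen initialization and, when a
validation split is supplied, returns the parameter state of the epoch
with the best validation AUROC (early model selection on the 4:1
train:validation split). Multi-label fine-tuning freezes the encoder:
each long sequence is windowed, final-layer hidden states are mean-pooled
over real token positions within each window and averaged across
windows, and an independent-sigmoid head (one logit per compartment,
threshold 0.5) is trained full-batch with Adam on the pooled d-vectors.
"Mean pooling on the feature dimension" is read as pooling across
positions to one d-vector; collapsing d itself would destroy the
representation.

## Attention read-out

Token importance is the [CLS]-query attention summed over all H heads of
one layer (the final layer by default, configurable): α_j = Σ_h
softmax_j(q*ᵀk_j / √d_h). Two choices deserve note. First, the score
reuses the encoder's own attention logits, hence the per-head scale
√d_h rather than √d. Second, [CLS]/[SEP]/[PAD] are removed from the
candidate set and each head's row is renormalized over real tokens, so
Σ_j α_j = H exactly and nucleotide tracks reflect sequence positions
only. Summation is per layer, not across layers. Token scores convert to
nucleotide scores by averaging, at each nucleotide, the α of every token
covering it (fewer than k at the edges, which preserves totals in the
interior up to O(k) edge effects).

Mutation maps score every single-nucleotide substitution as
P(mutant) − P(wild-type) under a fine-tuned binary head; reference cells
are identically 0 and negative values mark disruptive substitutions.

## Motif discovery

Per positive sequence, high-attention regions are maximal runs of
nucleotides with score ≥ mean + 1 SD of that sequence's own track (an
explicit cutoff or quantile can be substituted); runs shorter than 7 nt
are extended symmetrically to 7 and overlapping extensions merge. 7-mers
inside these regions are candidates, counted as presence/absence per
sequence — the hypergeometric sampling model needs exchangeable units,
so multiplicity is ignored. Significance uses a one-sided hypergeometric
tail against the negative control set: the population is all N
sequences, K = (positives carrying the 7-mer within high attention) +
(negatives carrying it anywhere), n = the positives, x = the foreground
carriers. An earlier design that counted the background over *all*
sequences' full lengths was abandoned after measurement: for a motif
genuinely concentrated in positives, that null already contains every
positive occurrence, the observed foreground sits at its expectation
(p ≈ 0.6 for a planted consensus on a trained model), and no true motif
can ever reach significance. Enrichment against the negative set is the
standard over-representation design and is what the procedure needs to
be informative. p-values receive Benjamini–Hochberg step-up correction
with significance at adjusted p < 0.005. Significant candidates merge
greedily: the most frequent candidate seeds a cluster and absorbs any
candidate alignable at offset ≤ 2 with ≤ 1 mismatch in the overlap
(ties in frequency break lexicographically). Clusters become
column-stochastic 4 × w PWMs with members weighted by their foreground
counts; consensus ties break A < C < G < U. PWMs export in MEME minimal
format for downstream comparison tools.

## Evaluation

AUROC uses the Mann–Whitney rank statistic with half-credit ties; AUPRC
uses step-wise precision–recall integration (no interpolation); F1, MCC
and accuracy come from the 0.5-thresholded confusion matrix.
Single-class inputs raise an error rather than returning NaN.
Positional enrichment expresses a site as its 1-based position divided
by the sequence length (position 10 on a 50-nt 3'UTR → 0.2), bins the
relative axis, computes per-bin fractions of sites whose attention
exceeds a threshold (default 0.3), and reports the Pearson correlation
of fraction against bin midpoint; a constant fraction vector is flagged
and reported as r = 0. Cross-validation is stratified k-fold with the
test fold never shown to the trainer.

## Synthetic data

Generators are pure functions of a spec and a seed. Background sequences
are i.i.d. draws from a stated base composition, AU-rich by default
(A 0.30, C 0.20, G 0.20, U 0.30), approximating human 3'UTR composition.
Motifs are planted by overwriting a sampled instance (IUPAC consensus or
PWM) at a uniform, fixed, or near-end position, and every plant is
recorded as a ground-truth interval.

Task geometries mirror the real benchmarks: RBP windows are 100 nt with
a 1:2 positive:negative ratio, split 80/20 train:test with 4:1
train:validation inside the 80%; m6A windows are 41 nt with the
adenosine fixed at position 21 (1-based) and an RRACH-compatible context
(R and H drawn uniformly within their IUPAC sets) in positives, balanced
1:1; localization records concatenate the first 4000 and last 4000 nt of
each transcript, carry independent multi-hot labels over six
compartments (nucleus, exosome, cytosol, ribosome, membrane, ER), and
plant one distinct motif per active compartment. Negatives are pure
background by default; a confusable-negative mode plants a one-mismatch
decoy to emulate shared sequence patterns between classes. The
pre-training corpus sprinkles a small set of recurring motifs (including
the RBP consensus) into background so the MLM has learnable structure.

What the generator does *not* emulate: positional biases of real
crosslink sites, read-count noise, secondary structure, homology between
sequences, and realistic motif degeneracy beyond IUPAC sampling. Passing
the planted-recovery tests therefore demonstrates that the machinery —
tokenization, masking, training, attention read-out, enrichment — is
correct and connected, not that the model attains published performance
on real CLIP/m6A/localization data.

## The desk-scale reference study

The packaged end-to-end study (`utrlm.pipeline.planted_motif_study`, also
driven by `scripts/acceptance.py`) runs on one CPU in about two minutes:
a 200-sequence corpus of 120-nt sequences pre-trained for 300 steps; a
150-positive / 300-negative 100-nt RBP-style dataset with the UGUAUAU
(PUM2-like) consensus planted in 90% of positives; the tiny encoder at
k = 6; 12 fine-tuning epochs with validation-based model selection, once
from the pre-trained state and once from random initialization; held-out
evaluation; and motif discovery on the training positives. k = 6 is the
deliberate choice at this scale: with two layers and d = 32 trained on a
few hundred windows, composition across several common tokens (as k = 3
requires in an AU-rich background, where UGU and UAU are frequent words)
is not reliably learnable, whereas at k = 6 the planted consensus maps
to near-unique vocabulary words and the study probes the pipeline rather
than the capacity ceiling of a deliberately tiny model. The plant rate
of 0.9 caps attainable held-out AUROC near 0.95, since unplanted
positives are indistinguishable from background. The localization
recovery test plants motifs densely (20 instances per active
compartment in 300–700-nt sequences) because mean pooling over hundreds
of positions at d = 32 dilutes sparser signals below the linear head's
detection floor; real zipcode elements are far sparser, which is
precisely why the full-scale model pools over richer representations.

## Known limitations

* The NumPy encoder is single-threaded-friendly and exact, not fast;
  full-scale (12 × 768) pre-training is out of reach by design.
* CLS-attention tracks from the tiny fine-tuned model are only weakly
  localized (the planted span scores ~1.1–1.3× the sequence mean);
  enrichment against negatives is what makes motif recovery sharp.
* The greedy redundancy filter is an ungapped identity proxy, not a
  clustering tool; it is deterministic and documented, nothing more.
* Checkpoints store parameters as `.npz` plus a JSON config; they are
  runtime artifacts, not exchange formats.
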