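"""[CLS]-attention importance scores, nucleotide tracks, and mutation maps.

The per-token importance of token j is the [CLS]-query attention to j,
summed over all H heads of one encoder layer (the final layer by
default):

    alpha_j = sum_h softmax_j(q*^T k_j / sqrt(d_h))

Special tokens ([CLS], [SEP], [PAD]) are removed from the candidate set
and each head's row is renormalized over the real tokens, so
sum_j alpha_j = H exactly. Token scores are converted to nucleotide
scores by averaging, at each nucleotide, the scores of every k-mer token
covering it (fewer than k at the sequence edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model
from .seq_io import Interval
from .tokenizer import TokenizedWindow, Vocabulary, encode_sequence


@dataclass(frozen=True)
class AttentionProfile:
    token_scores: np.ndarray  # (J,) alpha_j over real tokens
    nucleotide_scores: np.ndarray  # (L,)
    layer_used: int
    n_heads: int
    n_tokens: int


@dataclass(frozen=True)
class MutationMap:
    """Per-position, per-base change in classifier probability.

    delta[(i, b)] = P(mutant with base b at i) - P(wild-type); reference
    cells are exactly 0; base order is A, C, G, U.
    """

    delta: np.ndarray  # (L, 4)
    wildtype_score: float
    sequence: str


def cls_attention(state: model.EncoderState, layer: int = -1) -> np.ndarray:
    """alpha_j for each real token j from one layer's attention maps."""
    n_layers = len(state.attention)
    if not -n_layers <= layer < n_layers:
        raise IndexError(f"layer {layer} out of range for {n_layers} layers")
    A = state.attention[layer]  # (H, T, T)
    real = slice(1, 1 + state.n_real_tokens)
    rows = A[:, 0, real]  # [CLS] query attention to real tokens, per head
    rows = rows / rows.sum(axis=1, keepdims=True)  # drop special-token mass
    return rows.sum(axis=0)


def token_to_nucleotide(token_scores: np.ndarray, k: int, L: int) -> np.ndarray:
    """score(nt i) = mean of token scores over tokens covering nucleotide i."""
    J = token_scores.shape[0]
    if J != L - k + 1:
        raise ValueError(f"expected {L - k + 1} token scores for L={L}, k={k}")
    out = np.empty(L)
    for i in range(L):
        lo = max(0, i - k + 1)
        hi = min(i, J - 1)
        out[i] = token_scores[lo : hi + 1].mean()
    return out


def attention_profile(
    params: dict,
    config: model.ModelConfig,
    window: TokenizedWindow,
    k: int,
    layer: int = -1,
) -> AttentionProfile:
    """Encode a window and derive its token and nucleotide score tracks."""
    state = model.encode_window(params, config, window)
    tok = cls_attention(state, layer=layer)
    J = window.n_real_tokens
    L = J + k - 1
    return AttentionProfile(
        token_scores=tok,
        nucleotide_scores=token_to_nucleotide(tok, k, L),
        layer_used=layer if layer >= 0 else len(state.attention) + layer,
        n_heads=config.n_heads,
        n_tokens=J,
    )


def attention_landscape(
    params: dict,
    config: model.ModelConfig,
    windows: list[TokenizedWindow],
    labels: list[int] | np.ndarray,
    k: int,
    layer: int = -1,
) -> dict[int, np.ndarray]:
    """Column-wise mean nucleotide score per label class (aligned windows)."""
    labels = np.asarray(labels)
    tracks: dict[int, list[np.ndarray]] = {}
    for w, lab in zip(windows, labels):
        prof = attention_profile(params, config, w, k, layer=layer)
        tracks.setdefault(int(lab), []).append(prof.nucleotide_scores)
    return {lab: np.mean(np.stack(ts), axis=0) for lab, ts in tracks.items()}


def mutation_map(
    params: dict,
    config: model.ModelConfig,
    sequence: str,
    vocab: Vocabulary,
) -> MutationMap:
    """Saturation in-silico mutagenesis under a fine-tuned binary head.

    Negative deltas mark substitutions that reduce the predicted
    probability, i.e. disruptive mutations.
    """
    if "N" in sequence:
        raise ValueError("mutation map requires an unambiguous sequence")
    bases = "ACGU"
    wt_window = encode_sequence(sequence, vocab, config.max_positions)
    wt = model.classify_window(params, config, wt_window)
    L = len(sequence)
    delta = np.zeros((L, 4))
    for i in range(L):
        for bi, b in enumerate(bases):
            if b == sequence[i]:
                continue
            mut = sequence[:i] + b + sequence[i + 1 :]
            w = encode_sequence(mut, vocab, config.max_positions)
            delta[i, bi] = model.classify_window(params, config, w) - wt
    return MutationMap(delta=delta, wildtype_score=wt, sequence=sequence)


def write_nucleotide_track(
    profile: AttentionProfile, seq_id: str, path
) -> None:
    """BED-graph-style TSV: seq_id, start, end, score per nucleotide."""
    with open(path, "w") as fh:
        for i, s in enumerate(profile.nucleotide_scores):
            fh.write(f"{seq_id}\t{i}\t{i + 1}\t{s:.6g}\n")


def write_mutation_map(mm: MutationMap, path) -> None:
    """L x 4 TSV in base order A, C, G, U, one row per position."""
    with open(path, "w") as fh:
        fh.write("pos\tref\tA\tC\tG\tU\n")
        for i, row in enumerate(mm.delta):
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{i}\t{mm.sequence[i]}\t{vals}\n")
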