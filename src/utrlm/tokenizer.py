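"""k-mer vocabulary and sequence <-> token-id conversion.

A sequence is tokenized into overlapping k-mers at stride 1, so a length-L
sequence yields L - k + 1 tokens and adjacent tokens share k - 1 bases.
The vocabulary holds all 4^k k-mers plus five special tokens; windows are
framed as [CLS] t1 ... tn [SEP] [PAD]... up to a fixed model length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_io import Interval

BASES = "ACGU"  # lexicographic order A < C < G < U
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
PAD, UNK, CLS, SEP, MASK = range(5)


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional token <-> id maps for one k-mer size.

    Specials occupy ids 0-4 in the order [PAD], [UNK], [CLS], [SEP], [MASK]
    ([PAD] = 0 so padded id arrays are zero-filled); k-mers follow in
    lexicographic A < C < G < U order. Size is 4**k + 5.
    """

    k: int
    tokens: tuple[str, ...]
    token_to_id: dict[str, int] = field(repr=False)
    pad_id: int = PAD
    unk_id: int = UNK
    cls_id: int = CLS
    sep_id: int = SEP
    mask_id: int = MASK

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_kmers(self) -> int:
        return len(self.tokens) - len(SPECIAL_TOKENS)

    @property
    def first_kmer_id(self) -> int:
        return len(SPECIAL_TOKENS)

    def id_to_token(self, i: int) -> str:
        return self.tokens[i]

    def save(self, path: str | Path) -> None:
        """One token per line; a token's id is its line number (0-based)."""
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = tuple(Path(path).read_text().splitlines())
        if tokens[: len(SPECIAL_TOKENS)] != SPECIAL_TOKENS:
            raise ValueError(f"{path}: special tokens missing or out of order")
        k = len(tokens[len(SPECIAL_TOKENS)])
        return cls(k=k, tokens=tokens, token_to_id={t: i for i, t in enumerate(tokens)})


def build_vocabulary(k: int) -> Vocabulary:
    """All 4^k k-mers plus the five special tokens, deterministic order."""
    if not 3 <= k <= 6:
        raise ValueError(f"k must be in [3, 6], got {k}")
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    tokens = SPECIAL_TOKENS + tuple(kmers)
    return Vocabulary(k=k, tokens=tokens, token_to_id={t: i for i, t in enumerate(tokens)})


def tokenize(sequence: str, k: int, stride: int = 1) -> list[str]:
    """Overlapping k-mers left to right; any window touching N becomes [UNK]."""
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k = {k}"
        )
    out = []
    for i in range(0, len(sequence) - k + 1, stride):
        kmer = sequence[i : i + k]
        out.append("[UNK]" if "N" in kmer else kmer)
    return out


def reconstruct(tokens: list[str], k: int) -> str:
    """Reassemble a stride-1 tokenization (inverse of tokenize on N-free input)."""
    if not tokens:
        raise ValueError("no tokens to reconstruct")
    return tokens[0] + "".join(t[-1] for t in tokens[1:])


@dataclass(frozen=True)
class TokenizedWindow:
    """One model-ready window: fixed-length id vector plus bookkeeping."""

    ids: np.ndarray  # shape (max_positions,), int64
    n_real_tokens: int
    source: Interval | None = None

    def __post_init__(self) -> None:
        if self.ids[0] != CLS:
            raise ValueError("window must start with [CLS]")
        sep_pos = 1 + self.n_real_tokens
        if self.ids[sep_pos] != SEP:
            raise ValueError("[SEP] must immediately follow the last real token")
        if np.any(self.ids[sep_pos + 1 :] != PAD):
            raise ValueError("only [PAD] may follow [SEP]")

    @property
    def real_slice(self) -> slice:
        """Positions of the real k-mer tokens within `ids`."""
        return slice(1, 1 + self.n_real_tokens)


def encode(
    tokens: list[str],
    vocab: Vocabulary,
    max_positions: int,
    source: Interval | None = None,
) -> TokenizedWindow:
    """[CLS] + token ids + [SEP], right-padded with [PAD] to max_positions."""
    if not tokens:
        raise ValueError("cannot encode an empty token list")
    if len(tokens) + 2 > max_positions:
        raise ValueError(
            f"{len(tokens)} tokens + [CLS]/[SEP] exceed max_positions = "
            f"{max_positions}; split the sequence into windows first"
        )
    ids = np.full(max_positions, PAD, dtype=np.int64)
    ids[0] = CLS
    for j, tok in enumerate(tokens, start=1):
        ids[j] = vocab.token_to_id.get(tok, UNK)
    ids[len(tokens) + 1] = SEP
    return TokenizedWindow(ids=ids, n_real_tokens=len(tokens), source=source)


def decode(window: TokenizedWindow, vocab: Vocabulary) -> list[str]:
    """Token strings of the real tokens (inverse of encode)."""
    return [vocab.id_to_token(int(i)) for i in window.ids[window.real_slice]]


def encode_sequence(
    sequence: str,
    vocab: Vocabulary,
    max_positions: int,
    source: Interval | None = None,
) -> TokenizedWindow:
    """Convenience: tokenize at stride 1 and encode in one step."""
    return encode(tokenize(sequence, vocab.k), vocab, max_positions, source)


def token_span(token_index: int, k: int) -> tuple[int, int]:
    """Nucleotide half-open span covered by real token j: [j, j + k)."""
    if token_index < 0:
        raise ValueError("token index must be >= 0")
    return token_index, token_index + k
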