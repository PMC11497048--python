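"""Synthetic benchmark data with full ground truth.

Every input the pipeline needs is generated here: i.i.d. background
sequences of a stated base composition (AU-rich by default, as in human
3'UTRs), positives carrying instances of a planted consensus or PWM, and
the three task-shaped datasets:

* RBP windows: 100 nt, positives planted with a PUM2-like UGUAUAU
  consensus, negatives pure background at a 1:2 positive:negative ratio,
  split 80/20 train:test with 4:1 train:validation inside the 80%.
* m6A windows: 41 nt with an A fixed at the center (position 21,
  1-based); positives carry an RRACH-compatible context around the
  central adenosine; subsets are balanced 1:1.
* Localization sequences: long multi-label records built from the
  first 4000 + last 4000 nt of each transcript, each active compartment
  planting its own distinct motif.

Generators are pure functions of their spec and seed. Negatives are pure
background by default; a confusable-negative mode plants a one-mismatch
decoy to emulate shared sequence patterns between classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seq_io import Interval, SequenceRecord, window_sequence
from .tokenizer import TokenizedWindow, Vocabulary, encode, tokenize

BASES = "ACGU"
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
AU_RICH = (0.3, 0.2, 0.2, 0.3)  # A, C, G, U

LOCALIZATION_MOTIFS = {
    "nucleus": "CCACCAC",   # CCA-rich
    "exosome": "GCGGCGC",   # GC-rich
    "cytosol": "GAGGAGA",   # GA-rich
    "ribosome": "GCCGCCG",  # GC-rich variant
    "membrane": "CGACGAC",  # CGA-rich
    "ER": "GGGAGGG",        # GGG-rich
}


@dataclass(frozen=True)
class GeneratorSpec:
    n_sequences: int = 100
    length: int = 100
    composition: tuple[float, float, float, float] = AU_RICH
    motif: str | np.ndarray | None = "UGUAUAU"  # IUPAC consensus or 4 x w PWM
    plant_rate: float = 0.9
    plant_position: str = "uniform"  # "uniform" | "fixed:<i>" | "near-end"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.composition), 1.0, atol=1e-9):
            raise ValueError("base composition must sum to 1")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")


@dataclass(frozen=True)
class LabeledWindow:
    sequence: str
    label: int | np.ndarray
    ground_truth: Interval | None = None


@dataclass(frozen=True)
class DatasetSplits:
    train: list[LabeledWindow]
    val: list[LabeledWindow]
    test: list[LabeledWindow]

    @property
    def all(self) -> list[LabeledWindow]:
        return self.train + self.val + self.test


def generate_background(
    spec: GeneratorSpec, rng: np.random.Generator | None = None, prefix: str = "bg"
) -> list[SequenceRecord]:
    """i.i.d. sequences from the base composition; deterministic given seed."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    probs = np.asarray(spec.composition)
    return [
        SequenceRecord(
            f"{prefix}_{i}",
            "".join(
                np.array(list(BASES))[rng.choice(4, size=spec.length, p=probs)]
            ),
        )
        for i in range(spec.n_sequences)
    ]


def sample_motif_instance(
    motif: str | np.ndarray, rng: np.random.Generator
) -> str:
    """Draw one instance from an IUPAC consensus or a 4 x w PWM."""
    if isinstance(motif, str):
        return "".join(rng.choice(list(IUPAC[c])) for c in motif)
    motif = np.asarray(motif)
    return "".join(
        BASES[rng.choice(4, p=motif[:, col] / motif[:, col].sum())]
        for col in range(motif.shape[1])
    )


def _plant_position(policy: str, L: int, w: int, rng: np.random.Generator) -> int:
    if policy == "uniform":
        return int(rng.integers(0, L - w + 1))
    if policy == "near-end":
        lo = max(0, L - w - max(1, L // 10))
        return int(rng.integers(lo, L - w + 1))
    if policy.startswith("fixed:"):
        pos = int(policy.split(":", 1)[1])
        if not 0 <= pos <= L - w:
            raise ValueError(f"fixed position {pos} does not fit motif of width {w}")
        return pos
    raise ValueError(f"unknown plant position policy {policy!r}")


def plant_motif(
    records: list[SequenceRecord],
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[SequenceRecord], list[Interval | None]]:
    """Write one motif instance into a plant_rate fraction of records.

    Returns the modified records and, per record, the ground-truth
    interval of the planted instance (None where nothing was planted).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.motif is None:
        return list(records), [None] * len(records)
    out, truth = [], []
    for rec in records:
        if rng.random() < spec.plant_rate:
            inst = sample_motif_instance(spec.motif, rng)
            pos = _plant_position(
                spec.plant_position, len(rec.sequence), len(inst), rng
            )
            seq = rec.sequence[:pos] + inst + rec.sequence[pos + len(inst) :]
            out.append(SequenceRecord(rec.id, seq, rec.source_alphabet))
            truth.append(Interval(rec.id, pos, pos + len(inst), name=inst))
        else:
            out.append(rec)
            truth.append(None)
    return out, truth


def _one_mismatch_decoy(motif: str, rng: np.random.Generator) -> str:
    """A consensus-like decoy differing at one position."""
    inst = list(sample_motif_instance(motif, rng))
    i = int(rng.integers(len(inst)))
    inst[i] = rng.choice([b for b in BASES if b != inst[i]])
    return "".join(inst)


def _stratified_split(
    items: list[LabeledWindow],
    labels: np.ndarray,
    rng: np.random.Generator,
    test_frac: float = 0.2,
    val_frac_of_train: float = 0.2,
) -> DatasetSplits:
    """80/20 train:test, then 4:1 train:validation inside the 80%."""
    train, val, test = [], [], []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        idx = rng.permutation(idx)
        n_test = int(round(test_frac * idx.size))
        n_val = int(round(val_frac_of_train * (idx.size - n_test)))
        test.extend(items[i] for i in idx[:n_test])
        val.extend(items[i] for i in idx[n_test : n_test + n_val])
        train.extend(items[i] for i in idx[n_test + n_val :])
    return DatasetSplits(train=train, val=val, test=test)


def make_rbp_dataset(
    n_pos: int = 150,
    neg_ratio: int = 2,
    length: int = 100,
    motif: str = "UGUAUAU",
    plant_rate: float = 0.9,
    composition: tuple = AU_RICH,
    confusable_negatives: bool = False,
    seed: int = 0,
) -> DatasetSplits:
    """100-nt RBP binding windows at a 1:2 positive:negative ratio."""
    rng = np.random.default_rng(seed)
    pos_spec = GeneratorSpec(
        n_sequences=n_pos, length=length, composition=composition,
        motif=motif, plant_rate=plant_rate, seed=seed,
    )
    pos_recs = generate_background(pos_spec, rng, prefix="pos")
    pos_recs, truth = plant_motif(pos_recs, pos_spec, rng)
    neg_spec = replace(pos_spec, n_sequences=n_pos * neg_ratio, motif=None)
    neg_recs = generate_background(neg_spec, rng, prefix="neg")
    if confusable_negatives:
        planted = []
        for rec in neg_recs:
            if rng.random() < plant_rate:
                decoy = _one_mismatch_decoy(motif, rng)
                pos = _plant_position("uniform", length, len(decoy), rng)
                seq = rec.sequence[:pos] + decoy + rec.sequence[pos + len(decoy) :]
                planted.append(SequenceRecord(rec.id, seq))
            else:
                planted.append(rec)
        neg_recs = planted
    items = [
        LabeledWindow(r.sequence, 1, t) for r, t in zip(pos_recs, truth)
    ] + [LabeledWindow(r.sequence, 0, None) for r in neg_recs]
    labels = np.array([w.label for w in items])
    return _stratified_split(items, labels, rng)


M6A_WINDOW = 41
M6A_CENTER = 20  # 0-based; position 21 in 1-based coordinates


def make_m6a_dataset(
    n_pos: int = 150,
    composition: tuple = AU_RICH,
    seed: int = 0,
) -> DatasetSplits:
    """41-nt A-centered windows, balanced 1:1 positive:negative.

    Positives carry an RRACH context with the central A as the methylated
    adenosine (context columns 19-23, 1-based); negatives are background
    with an A forced at the center.
    """
    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(
        n_sequences=n_pos, length=M6A_WINDOW, composition=composition, seed=seed
    )

    def _center_a(rec: SequenceRecord) -> str:
        s = rec.sequence
        return s[:M6A_CENTER] + "A" + s[M6A_CENTER + 1 :]

    pos_items = []
    for rec in generate_background(spec, rng, prefix="pos"):
        ctx = sample_motif_instance("RRACH", rng)  # R, H uniform over IUPAC
        s = _center_a(rec)
        start = M6A_CENTER - 2  # RR-A-CH: the A lands at the center
        s = s[:start] + ctx[:2] + "A" + ctx[3:] + s[start + 5 :]
        pos_items.append(
            LabeledWindow(s, 1, Interval(rec.id, start, start + 5, name="RRACH"))
        )
    neg_items = [
        LabeledWindow(_center_a(rec), 0, None)
        for rec in generate_background(
            replace(spec, n_sequences=n_pos), rng, prefix="neg"
        )
    ]
    items = pos_items + neg_items
    labels = np.array([w.label for w in items])
    return _stratified_split(items, labels, rng)


LOC_FLANK = 4000


def concat_first_last(sequence: str, flank: int = LOC_FLANK) -> str:
    """First `flank` nt plus last `flank` nt; shorter sequences pass whole.

    Sequences at or under 2 * flank are returned unchanged (padding to the
    model length happens at the token level with [PAD] ids).
    """
    if len(sequence) <= 2 * flank:
        return sequence
    return sequence[:flank] + sequence[-flank:]


def make_localization_dataset(
    n_sequences: int = 60,
    length_range: tuple[int, int] = (3000, 10000),
    label_prob: float = 0.35,
    instances_per_label: int = 2,
    composition: tuple = AU_RICH,
    seed: int = 0,
) -> list[LabeledWindow]:
    """Multi-label localization sequences with compartment-specific motifs.

    Each record draws an independent Bernoulli(label_prob) bit per
    compartment (at least one active) and plants that compartment's motif
    `instances_per_label` times at uniform positions in the concatenated
    first-4000 + last-4000 sequence.
    """
    rng = np.random.default_rng(seed)
    names = list(LOCALIZATION_MOTIFS)
    out: list[LabeledWindow] = []
    probs = np.asarray(composition)
    for i in range(n_sequences):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        raw = "".join(np.array(list(BASES))[rng.choice(4, size=L, p=probs)])
        seq = concat_first_last(raw)
        bits = (rng.random(len(names)) < label_prob).astype(int)
        if bits.sum() == 0:
            bits[int(rng.integers(len(names)))] = 1
        s = seq
        for j, name in enumerate(names):
            if bits[j]:
                motif = LOCALIZATION_MOTIFS[name]
                for _ in range(instances_per_label):
                    pos = _plant_position("uniform", len(s), len(motif), rng)
                    s = s[:pos] + motif + s[pos + len(motif) :]
        out.append(LabeledWindow(s, bits, None))
    return out


def make_pretrain_corpus(
    n_sequences: int = 200,
    length: int = 120,
    motifs: tuple[str, ...] = ("UGUAUAU", "GGACU", "AUUUA"),
    motif_rate: float = 0.9,
    composition: tuple = AU_RICH,
    vocab: Vocabulary | None = None,
    max_positions: int = 128,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[TokenizedWindow]]:
    """Background corpus with recurring motifs so the MLM has structure.

    Each motif is planted once per sequence with probability `motif_rate`
    at a uniform position. When a vocabulary is given, sequences are also
    windowed and encoded to the model length.
    """
    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(
        n_sequences=n_sequences, length=length, composition=composition, seed=seed
    )
    records = []
    for rec in generate_background(spec, rng, prefix="utr"):
        s = rec.sequence
        for motif in motifs:
            if rng.random() < motif_rate:
                pos = _plant_position("uniform", len(s), len(motif), rng)
                s = s[:pos] + motif + s[pos + len(motif) :]
        records.append(SequenceRecord(rec.id, s))
    windows: list[TokenizedWindow] = []
    if vocab is not None:
        windows = encode_records(records, vocab, max_positions)
    return records, windows


def encode_records(
    records: list[SequenceRecord], vocab: Vocabulary, max_positions: int
) -> list[TokenizedWindow]:
    """Window each record to fit the model and encode every fragment.

    The nucleotide window is max_positions - 2 + (k - 1), so a full
    window tokenizes to exactly max_positions - 2 real tokens; final
    short fragments are padded at the token level by `encode`.
    """
    window_nt = max_positions - 2 + vocab.k - 1
    out: list[TokenizedWindow] = []
    for rec in records:
        for frag, iv in window_sequence(rec, window_nt):
            if len(frag) < vocab.k:
                continue  # tail shorter than one k-mer carries no token
            out.append(encode(tokenize(frag, vocab.k), vocab, max_positions, iv))
    return out


def windows_to_tokenized(
    items: list[LabeledWindow], vocab: Vocabulary, max_positions: int
) -> list[tuple[TokenizedWindow, int]]:
    """Encode equal-length labeled windows for binary fine-tuning."""
    out = []
    for item in items:
        tokens = tokenize(item.sequence, vocab.k)
        out.append((encode(tokens, vocab, max_positions), int(item.label)))
    return out
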