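"""Attention-guided motif discovery.

High-attention nucleotide regions of positive sequences are scanned for
7-mer candidates; each candidate's over-representation is scored with a
one-sided hypergeometric test against the negative control set (a
positive sequence "carries" a candidate when a high-attention region
contains it; a negative carries it anywhere along its length; the
population is all sequences), corrected with Benjamini-Hochberg, and
significant candidates (adjusted p < 0.005) are greedily merged into
clusters that are rendered as position weight matrices and exported in
MEME minimal format.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .attention import AttentionProfile
from .seq_io import Interval

BASES = "ACGU"
DEFAULT_WIDTH = 7
DEFAULT_ALPHA = 0.005


@dataclass
class MotifCandidate:
    kmer: str
    fg_count: int  # positive sequences containing it in high-attention regions
    bg_count: int  # background sequences containing it anywhere
    p_value: float = 1.0
    q_value: float = 1.0
    significant: bool = False


@dataclass(frozen=True)
class PWM:
    """Column-stochastic 4 x w frequency matrix, row order A, C, G, U."""

    matrix: np.ndarray
    n_instances: int
    consensus: str

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MotifCluster:
    # members: (kmer, offset relative to the seed frame, weight)
    members: list[tuple[str, int, int]]

    @property
    def seed(self) -> str:
        return self.members[0][0]

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.members)


def high_attention_regions(
    profile: AttentionProfile,
    cutoff: float | None = None,
    min_width: int = DEFAULT_WIDTH,
) -> list[Interval]:
    """Maximal runs of nucleotides with score >= cutoff.

    Default cutoff is the per-sequence mean + 1 SD; a strictly positive SD
    is required for any region to emerge from a constant profile. Runs
    shorter than `min_width` are extended symmetrically (clipped at the
    sequence ends); overlapping extended runs merge.
    """
    scores = profile.nucleotide_scores
    if scores.size == 0:
        raise ValueError("empty attention profile")
    L = scores.size
    if cutoff is None:
        sd = scores.std()
        if sd == 0:
            return []
        cutoff = scores.mean() + sd
    above = scores >= cutoff
    regions: list[list[int]] = []
    i = 0
    while i < L:
        if above[i]:
            j = i
            while j + 1 < L and above[j + 1]:
                j += 1
            start, end = i, j + 1
            if end - start < min_width:
                pad = min_width - (end - start)
                start = max(0, start - pad // 2)
                end = min(L, start + min_width)
                start = max(0, end - min_width)
            if regions and start <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], end)
            else:
                regions.append([start, end])
            i = j + 1
        else:
            i += 1
    return [Interval("profile", s, e, name=f"har:{s}-{e}") for s, e in regions]


def _kmers_in(seq: str, width: int) -> set[str]:
    return {
        seq[i : i + width]
        for i in range(len(seq) - width + 1)
        if "N" not in seq[i : i + width]
    }


def count_candidates(
    positive_regions: list[list[Interval]],
    positive_sequences: list[str],
    negative_sequences: list[str],
    width: int = DEFAULT_WIDTH,
) -> list[MotifCandidate]:
    """Presence/absence counts per 7-mer.

    Foreground: a positive sequence counts once for a k-mer if any of its
    high-attention regions contains it. Background: the negative control
    set, counted over whole sequences.
    """
    fg = Counter()
    for regions, seq in zip(positive_regions, positive_sequences):
        seen: set[str] = set()
        for iv in regions:
            seen |= _kmers_in(seq[iv.start : iv.end], width)
        fg.update(seen)
    bg = Counter()
    for seq in negative_sequences:
        bg.update(_kmers_in(seq, width))
    return [
        MotifCandidate(kmer=k, fg_count=c, bg_count=bg.get(k, 0))
        for k, c in sorted(fg.items())
    ]


def hypergeom_enrich(x: int, n_fg: int, K: int, N_total: int) -> float:
    """One-sided over-representation tail P(X >= x).

    Population N_total sequences, K of which contain the k-mer; n_fg
    positive sequences drawn; x of them contain it in high attention.
    """
    if min(x, n_fg, K, N_total) < 0:
        raise ValueError("counts must be non-negative")
    if x > min(K, n_fg):
        raise ValueError(f"x = {x} exceeds min(K = {K}, n = {n_fg})")
    return float(hypergeom.sf(x - 1, N_total, K, n_fg))


def bh_correct(
    p_values: np.ndarray | list[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance calls.

    q_i = min over ranks j >= i of (m * p_(j) / j), capped at 1; a
    candidate is called significant iff its q-value is below alpha.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q = np.empty(m)
    q[order] = adj
    return q, q < alpha


def score_candidates(
    candidates: list[MotifCandidate],
    n_fg: int,
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
) -> list[MotifCandidate]:
    """Attach hypergeometric p-values and BH q-values in place.

    Population: n_total sequences of which K = fg_count + bg_count carry
    the k-mer (attention-restricted in positives, anywhere in negatives);
    n_fg positives are drawn and x = fg_count of them carry it.
    """
    for c in candidates:
        K = c.fg_count + c.bg_count
        c.p_value = hypergeom_enrich(c.fg_count, n_fg, K, n_total)
    q, sig = bh_correct([c.p_value for c in candidates], alpha=alpha)
    for c, qv, s in zip(candidates, q, sig):
        c.q_value = float(qv)
        c.significant = bool(s)
    return candidates


def _align(a: str, b: str, max_offset: int = 2, max_mismatch: int = 1):
    """Best (offset, mismatches) aligning b against a, or None.

    Positive offset shifts b rightward relative to a; the overlap must
    have at most `max_mismatch` mismatches.
    """
    best = None
    for off in range(-max_offset, max_offset + 1):
        lo = max(0, off)
        hi = min(len(a), len(b) + off)
        if hi - lo < len(a) - max_offset:  # demand a substantial overlap
            continue
        mm = sum(a[i] != b[i - off] for i in range(lo, hi))
        if mm <= max_mismatch and (best is None or (mm, abs(off)) < best[1:]):
            best = (off, mm, abs(off))
    return None if best is None else (best[0], best[1])


def merge_candidates(
    significant: list[MotifCandidate],
    max_offset: int = 2,
    max_mismatch: int = 1,
) -> list[MotifCluster]:
    """Greedy clustering: seed with the most frequent candidate, absorb
    everything alignable with offset <= 2 and <= 1 mismatch, repeat."""
    remaining = sorted(significant, key=lambda c: (-c.fg_count, c.kmer))
    clusters: list[MotifCluster] = []
    while remaining:
        seed = remaining.pop(0)
        members = [(seed.kmer, 0, seed.fg_count)]
        rest = []
        for c in remaining:
            hit = _align(seed.kmer, c.kmer, max_offset, max_mismatch)
            if hit is not None:
                members.append((c.kmer, hit[0], c.fg_count))
            else:
                rest.append(c)
        remaining = rest
        clusters.append(MotifCluster(members=members))
    return clusters


def build_pwm(
    instances: list[str] | MotifCluster,
    weights: list[int] | None = None,
    width: int | None = None,
) -> PWM:
    """Column base frequencies of aligned instances.

    Accepts either pre-aligned equal-length strings (optionally weighted)
    or a MotifCluster, whose members contribute at their alignment offsets
    within the seed frame. Consensus ties break lexicographically
    (A < C < G < U).
    """
    if isinstance(instances, MotifCluster):
        cluster = instances
        w = width or len(cluster.seed)
        counts = np.zeros((4, w))
        total = 0
        for kmer, off, wt in cluster.members:
            for col in range(w):
                src = col - off
                if 0 <= src < len(kmer):
                    counts[BASES.index(kmer[src]), col] += wt
            total += wt
        n_instances = total
    else:
        if not instances:
            raise ValueError("no instances")
        w = width or len(instances[0])
        if any(len(s) != w for s in instances):
            raise ValueError("instances must be aligned to equal length")
        weights = weights or [1] * len(instances)
        counts = np.zeros((4, w))
        for s, wt in zip(instances, weights):
            for col, base in enumerate(s):
                counts[BASES.index(base), col] += wt
        n_instances = sum(weights)
    colsum = counts.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("a PWM column received no instances")
    matrix = counts / colsum
    consensus = "".join(BASES[int(np.argmax(matrix[:, c]))] for c in range(w))
    return PWM(matrix=matrix, n_instances=int(n_instances), consensus=consensus)


# --------------------------------------------------------------- MEME IO


def write_meme(pwms: list[PWM], path: str | Path, names: list[str] | None = None):
    """MEME minimal motif format over the ACGU alphabet."""
    names = names or [f"motif_{i + 1}" for i in range(len(pwms))]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("strands: +\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n"
        )
        for name, pwm in zip(names, pwms):
            fh.write(f"MOTIF {name} {pwm.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {pwm.n_instances} E= 0\n"
            )
            for col in range(pwm.width):
                fh.write(
                    " ".join(f"{pwm.matrix[r, col]:.6f}" for r in range(4)) + "\n"
                )
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal file back into PWMs (for round-trip checks)."""
    pwms: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("letter-probability matrix:"):
            w = int(lines[i].split("w=")[1].split()[0])
            ns = int(lines[i].split("nsites=")[1].split()[0])
            rows = [
                [float(x) for x in lines[i + 1 + c].split()] for c in range(w)
            ]
            matrix = np.array(rows).T
            matrix = matrix / matrix.sum(axis=0)
            consensus = "".join(
                BASES[int(np.argmax(matrix[:, c]))] for c in range(w)
            )
            pwms.append(PWM(matrix=matrix, n_instances=ns, consensus=consensus))
            i += w + 1
        else:
            i += 1
    return pwms


def write_candidate_table(candidates: list[MotifCandidate], path: str | Path):
    with open(path, "w") as fh:
        fh.write("kmer\tfg_count\tbg_count\tp_value\tq_value\tsignificant\n")
        for c in sorted(candidates, key=lambda c: c.p_value):
            fh.write(
                f"{c.kmer}\t{c.fg_count}\t{c.bg_count}\t{c.p_value:.4g}\t"
                f"{c.q_value:.4g}\t{int(c.significant)}\n"
            )
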