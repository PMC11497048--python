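"""Span-contiguous masking plans for masked-language-model pre-training.

With overlapping stride-1 k-mers, masking single tokens is trivial to
invert: a hidden k-mer can be read off its unmasked neighbours. Masking
is therefore applied in contiguous spans of up to k tokens (the k tokens
whose windows overlap an anchor k-mer), so that at least one nucleotide
inside each full span is covered by no unmasked token.

Positions in a plan are 0-based indices among the *real* tokens of a
window (the [CLS] offset is handled when a plan is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tokenizer import TokenizedWindow, Vocabulary

ACTION_MASK = "MASK"
ACTION_RANDOM = "RANDOM"
ACTION_KEEP = "KEEP"


@dataclass(frozen=True)
class MaskingPlan:
    """Masked real-token positions, their spans, and per-token actions.

    `actions` maps position -> (ACTION_MASK, None) | (ACTION_RANDOM, token id)
    | (ACTION_KEEP, None). Random replacement ids are drawn at planning time
    so a plan fully determines the corruption.
    """

    masked_positions: tuple[int, ...]
    spans: tuple[tuple[int, int], ...]  # half-open runs of masked positions
    actions: dict[int, tuple[str, int | None]]
    seed: int | None = None

    def to_text(self) -> str:
        """Serialize for reproducibility audits (one position per line)."""
        lines = [f"# seed={self.seed}"]
        for pos in self.masked_positions:
            act, repl = self.actions[pos]
            lines.append(f"{pos}\t{act}\t{'' if repl is None else repl}")
        return "\n".join(lines) + "\n"


def _spans_from_positions(positions: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Maximal runs (half-open) of a sorted position array."""
    if positions.size == 0:
        return ()
    breaks = np.nonzero(np.diff(positions) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [positions.size - 1]))
    return tuple(
        (int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)
    )


def plan_masking(
    window: TokenizedWindow,
    vocab: Vocabulary,
    k: int | None = None,
    mask_rate: float = 0.15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    anchors: list[int] | None = None,
) -> MaskingPlan:
    """Draw a span-contiguous masking plan over a window's real tokens.

    Anchors (masked-k-mer start positions) are drawn uniformly without
    replacement; each expands to the k contiguous token positions starting
    at the anchor, clipped at the sequence end and truncated once the
    budget round(mask_rate * n_real_tokens) is met. Overlapping spans
    merge. Per masked token the replacement action is 80% [MASK], 10% a
    random k-mer token, 10% keep. [UNK] tokens are never masked.

    `anchors` forces the anchor order (for audits and worked examples);
    actions are still drawn from the rng.
    """
    if not 0.0 <= mask_rate < 1.0:
        raise ValueError(f"mask_rate must be in [0, 1), got {mask_rate}")
    k = k if k is not None else vocab.k
    n = window.n_real_tokens
    if n < k:
        raise ValueError(f"window has {n} real tokens, fewer than k = {k}")
    if rng is None:
        rng = np.random.default_rng(seed)

    real_ids = window.ids[window.real_slice]
    maskable = np.nonzero(real_ids != vocab.unk_id)[0]
    budget = int(round(mask_rate * n))
    if budget == 0 or maskable.size == 0:
        return MaskingPlan((), (), {}, seed)

    if anchors is None:
        anchor_order = rng.permutation(maskable)
    else:
        anchor_order = np.asarray(anchors, dtype=np.int64)

    chosen: set[int] = set()
    for a in anchor_order:
        if len(chosen) >= budget:
            break
        for pos in range(int(a), min(int(a) + k, n)):
            if len(chosen) >= budget:
                break
            if real_ids[pos] != vocab.unk_id:
                chosen.add(pos)

    positions = np.array(sorted(chosen), dtype=np.int64)
    actions: dict[int, tuple[str, int | None]] = {}
    u = rng.random(positions.size)
    for pos, draw in zip(positions, u):
        if draw < 0.8:
            actions[int(pos)] = (ACTION_MASK, None)
        elif draw < 0.9:
            repl = int(rng.integers(vocab.first_kmer_id, len(vocab)))
            actions[int(pos)] = (ACTION_RANDOM, repl)
        else:
            actions[int(pos)] = (ACTION_KEEP, None)

    return MaskingPlan(
        masked_positions=tuple(int(p) for p in positions),
        spans=_spans_from_positions(positions),
        actions=actions,
        seed=seed,
    )


def apply_plan(
    window: TokenizedWindow, plan: MaskingPlan, vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corrupt a window according to a plan.

    Returns (corrupted ids, target ids, loss mask), all of model length.
    Targets equal the original ids everywhere; the loss mask is 1 exactly
    on the masked real-token positions (shifted past [CLS]).
    """
    if any(p >= window.n_real_tokens for p in plan.masked_positions):
        raise ValueError("plan positions exceed the window's real tokens")
    corrupted = window.ids.copy()
    targets = window.ids.copy()
    loss_mask = np.zeros_like(window.ids)
    for pos in plan.masked_positions:
        arr_pos = pos + 1  # skip [CLS]
        act, repl = plan.actions[pos]
        if act == ACTION_MASK:
            corrupted[arr_pos] = vocab.mask_id
        elif act == ACTION_RANDOM:
            corrupted[arr_pos] = repl
        loss_mask[arr_pos] = 1
    return corrupted, targets, loss_mask
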