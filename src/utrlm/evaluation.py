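"""Benchmark metrics, positional-enrichment statistics, and cross-validation.

The five binary-classification metrics are AUROC (Mann-Whitney rank
statistic, ties at half credit), AUPRC (step-wise precision-recall
integration), F1, MCC, and accuracy at a 0.5 threshold. Positional
enrichment expresses each annotated site as a relative distance
(1-based position / sequence length, so position 10 on a 50-nt sequence
is 0.2) and correlates the per-bin fraction of high-attention sites
with position along the 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .seq_io import Interval


@dataclass(frozen=True)
class MetricReport:
    auroc: float
    auprc: float
    f1: float
    mcc: float
    acc: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc, "auprc": self.auprc, "f1": self.f1,
            "mcc": self.mcc, "acc": self.acc,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC/AUPRC require both classes present")
    calls = (scores >= threshold).astype(int)
    return MetricReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, calls, zero_division=0)),
        mcc=float(matthews_corrcoef(labels, calls)),
        acc=float(accuracy_score(labels, calls)),
        n_pos=n_pos,
        n_neg=n_neg,
        threshold=threshold,
    )


def relative_position(position: int, length: int) -> float:
    """1-based site position scaled by sequence length, in (0, 1]."""
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside sequence of length {length}")
    return position / length


@dataclass(frozen=True)
class PositionalEnrichment:
    relative_positions: np.ndarray
    bin_midpoints: np.ndarray
    bin_site_counts: np.ndarray
    bin_fractions: np.ndarray  # fraction of sites above threshold per bin
    pearson_r: float
    p_value: float
    threshold: float
    constant: bool = False  # correlation undefined on a constant vector


def positional_enrichment(
    sites: list[Interval],
    seq_lengths: dict[str, int],
    attention_tracks: dict[str, np.ndarray],
    threshold: float = 0.3,
    n_bins: int = 10,
) -> PositionalEnrichment:
    """Fraction of high-attention sites as a function of relative position.

    Each site contributes its 1-based start position divided by its
    sequence length; a site is "high attention" when its nucleotide
    attention score exceeds `threshold`.
    """
    rel, high = [], []
    for site in sites:
        L = seq_lengths[site.seq_id]
        if site.start >= L:
            raise ValueError(f"site {site.name} beyond sequence {site.seq_id}")
        rel.append(relative_position(site.start + 1, L))
        high.append(attention_tracks[site.seq_id][site.start] > threshold)
    rel_arr = np.array(rel)
    high_arr = np.array(high, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(rel_arr, edges[1:-1]), 0, n_bins - 1)
    counts = np.zeros(n_bins)
    fracs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b] > 0:
            fracs[b] = high_arr[sel].mean()
    ok = ~np.isnan(fracs)
    constant = bool(np.unique(fracs[ok]).size <= 1 or ok.sum() < 2)
    if constant:
        r, p = 0.0, 1.0
    else:
        r, p = pearsonr(mids[ok], fracs[ok])
    return PositionalEnrichment(
        relative_positions=rel_arr,
        bin_midpoints=mids,
        bin_site_counts=counts,
        bin_fractions=fracs,
        pearson_r=float(r),
        p_value=float(p),
        threshold=threshold,
        constant=constant,
    )


def cross_validate(
    sequences: list,
    labels: np.ndarray,
    trainer,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[list[MetricReport], dict]:
    """Stratified k-fold cross-validation.

    `trainer(train_items, train_labels, test_items) -> test scores`; the
    test fold is never shown to the trainer with labels. Returns per-fold
    reports plus mean and SD of each metric.
    """
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        train_items = [sequences[i] for i in train_idx]
        test_items = [sequences[i] for i in test_idx]
        scores = trainer(train_items, labels[train_idx], test_items)
        reports.append(compute_metrics(np.asarray(scores), labels[test_idx]))
    summary = {}
    for name in ("auroc", "auprc", "f1", "mcc", "acc"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return reports, summary


def write_report_tsv(report: MetricReport, path) -> None:
    with open(path, "w") as fh:
        for key, val in report.to_dict().items():
            fh.write(f"{key}\t{val}\n")
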