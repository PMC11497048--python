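"""Pre-training and fine-tuning loops.

Optimization follows the BERT recipe: AdamW (decoupled weight decay,
beta1 = 0.9, beta2 = 0.98, eps = 1e-6, weight decay 0.01 on matrices and
embeddings, none on biases and layer-norm parameters) under a linear
warmup / linear decay learning-rate schedule, with gradient clipping at
global norm 1.0. The full-scale reference schedule warms up from 0 to
4e-4 over 10k steps and decays to 0 at 200k; desk-scale runs use the
same shape at smaller step counts. Masking is re-sampled every step
(dynamic masking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import masking, model
from .tokenizer import TokenizedWindow, Vocabulary


@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear learning rate: 0 -> peak over warmup, peak -> 0 after."""

    peak_lr: float = 4e-4
    warmup_steps: int = 10_000
    total_steps: int = 200_000

    def __post_init__(self) -> None:
        if not 0 < self.warmup_steps < self.total_steps:
            raise ValueError("require 0 < warmup_steps < total_steps")

    def lr_at(self, step: int) -> float:
        if step <= 0:
            return 0.0
        if step <= self.warmup_steps:
            return self.peak_lr * step / self.warmup_steps
        if step >= self.total_steps:
            return 0.0
        frac = (self.total_steps - step) / (self.total_steps - self.warmup_steps)
        return self.peak_lr * frac


def lr_at(schedule: Schedule, step: int) -> float:
    return schedule.lr_at(step)


@dataclass(frozen=True)
class OptimSpec:
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-6
    weight_decay: float = 0.01
    clip_norm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "eps", "weight_decay", "clip_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimizer over a param dict."""

    def __init__(self, params: dict[str, np.ndarray], spec: OptimSpec):
        self.spec = spec
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    @staticmethod
    def _decayed(name: str, value: np.ndarray) -> bool:
        # biases and layer-norm parameters are exempt from weight decay
        return value.ndim >= 2

    def step(self, params: dict, grads: dict, lr: float) -> None:
        s = self.spec
        gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, s.clip_norm / (gnorm + 1e-12))
        self.t += 1
        c1 = 1 - s.beta1**self.t
        c2 = 1 - s.beta2**self.t
        for k, p in params.items():
            g = grads[k] * scale
            self.m[k] = s.beta1 * self.m[k] + (1 - s.beta1) * g
            self.v[k] = s.beta2 * self.v[k] + (1 - s.beta2) * g**2
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + s.eps)
            if self._decayed(k, p):
                update = update + s.weight_decay * p
            p -= lr * update


def _stack_masked_batch(windows, vocab, k, mask_rate, rng):
    corr, tgt, lm = [], [], []
    for w in windows:
        plan = masking.plan_masking(w, vocab, k=k, mask_rate=mask_rate, rng=rng)
        c, t, m = masking.apply_plan(w, plan, vocab)
        corr.append(c); tgt.append(t); lm.append(m)
    return np.stack(corr), np.stack(tgt), np.stack(lm)


def pretrain(
    corpus: list[TokenizedWindow],
    vocab: Vocabulary,
    config: model.ModelConfig,
    schedule: Schedule,
    optim: OptimSpec,
    seed: int,
    batch_size: int = 16,
    mask_rate: float = 0.15,
    params: dict | None = None,
) -> tuple[dict, list[dict]]:
    """Masked-language-model pre-training.

    Each step samples a batch, draws a fresh masking plan per window,
    and takes one AdamW step on the MLM cross-entropy. Returns the
    parameters and a per-step history of (step, loss, lr).
    """
    if not corpus:
        raise ValueError("empty pre-training corpus")
    if batch_size > len(corpus):
        raise ValueError("batch size larger than corpus")
    rng = np.random.default_rng(seed)
    if params is None:
        params = model.init_params(config, seed=int(rng.integers(2**31)))
    opt = AdamW(params, optim)
    history: list[dict] = []
    for step in range(1, schedule.total_steps + 1):
        idx = rng.choice(len(corpus), size=batch_size, replace=False)
        batch = [corpus[i] for i in idx]
        corr, tgt, lm = _stack_masked_batch(batch, vocab, vocab.k, mask_rate, rng)
        loss, grads = model.mlm_loss_and_grads(
            params, config, corr, tgt, lm, train=True, rng=rng
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite MLM loss at step {step}")
        lr = schedule.lr_at(step)
        opt.step(params, grads, lr)
        history.append({"step": step, "loss": loss, "lr": lr})
    return params, history


def _val_auroc(params, config, val_set) -> float:
    from sklearn.metrics import roc_auc_score

    ids = np.stack([w.ids for w, _ in val_set])
    labels = np.array([lab for _, lab in val_set])
    return float(roc_auc_score(labels, model.classify_batch(params, config, ids)))


def finetune(
    params: dict,
    config: model.ModelConfig,
    dataset: list[tuple[TokenizedWindow, int]],
    schedule: Schedule,
    optim: OptimSpec,
    seed: int,
    batch_size: int = 16,
    epochs: int | None = None,
    val_set: list[tuple[TokenizedWindow, int]] | None = None,
) -> tuple[dict, list[dict]]:
    """End-to-end binary fine-tuning from a (pre-trained or random) init.

    Steps are `epochs` passes over the shuffled dataset, or
    schedule.total_steps batches when epochs is None. Labels must be 0/1.
    When a validation set is given, the per-epoch validation AUROC selects
    the returned parameter state (early model selection); otherwise the
    final state is returned.
    """
    if not dataset:
        raise ValueError("empty fine-tuning dataset")
    labels_all = np.array([lab for _, lab in dataset])
    if not set(np.unique(labels_all)) <= {0, 1}:
        raise ValueError("binary fine-tuning requires 0/1 labels")
    rng = np.random.default_rng(seed)
    params = {k: v.copy() for k, v in params.items()}
    opt = AdamW(params, optim)
    ids_all = np.stack([w.ids for w, _ in dataset])
    n = len(dataset)
    history: list[dict] = []
    step = 0
    best_val = -np.inf
    best_params = params
    if epochs is not None:
        order_epochs = epochs
    else:
        order_epochs = int(np.ceil(schedule.total_steps * batch_size / n))
    for _ in range(order_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            step += 1
            if epochs is None and step > schedule.total_steps:
                break
            loss, grads = model.classification_loss_and_grads(
                params, config, ids_all[sel], labels_all[sel], train=True, rng=rng
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at step {step}")
            lr = schedule.lr_at(min(step, schedule.total_steps))
            opt.step(params, grads, lr)
            history.append({"step": step, "loss": loss, "lr": lr})
        if val_set is not None:
            va = _val_auroc(params, config, val_set)
            history[-1]["val_auroc"] = va
            if va > best_val:
                best_val = va
                best_params = {k: v.copy() for k, v in params.items()}
        if epochs is None and step > schedule.total_steps:
            break
    return (best_params if val_set is not None else params), history


def finetune_multilabel(
    params: dict,
    config: model.ModelConfig,
    dataset: list[tuple[list[TokenizedWindow], np.ndarray]],
    seed: int,
    n_labels: int = 6,
    lr: float = 0.05,
    n_iter: int = 500,
) -> model.MultiLabelHead:
    """Multi-label head on frozen mean-pooled embeddings.

    The encoder parameters are not updated; each sample is a list of
    windows spanning one long sequence plus its multi-hot label vector.
    """
    X = np.stack([model.embed_long_sequence(params, config, ws) for ws, _ in dataset])
    Y = np.stack([y for _, y in dataset])
    head = model.MultiLabelHead(config.d_model, n_labels=n_labels, seed=seed)
    return head.fit(X, Y, lr=lr, n_iter=n_iter)


def write_history_tsv(history: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tloss\tlr\n")
        for row in history:
            fh.write(f"{row['step']}\t{row['loss']:.6f}\t{row['lr']:.8g}\n")
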