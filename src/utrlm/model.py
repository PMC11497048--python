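"""A BERT-style transformer encoder for k-mer token sequences, in NumPy.

Forward pass, analytic backward pass, the masked-language-model loss, and
the task heads ([CLS] binary classifier, frozen mean-pooled embedding
extractor, independent-sigmoid multi-label head) are implemented directly
on float64 arrays. The architecture is the standard post-norm encoder:

    X0 = dropout(token_emb[ids] + pos_emb)
    per layer:  X1 = LN(X + Wo . MultiHeadAttention(X))
                X2 = LN(X1 + FFN(X1)),   FFN(x) = GeLU(x W1 + b1) W2 + b2

with learned absolute positional embeddings, per-head scaled dot-product
attention (scale sqrt(d_h), d_h = d / H), and [PAD] key positions excluded
from every softmax. The default configuration is the full-scale model
(12 layers, 12 heads, d = 768, FFN 3072, 512 positions); desk-scale work
uses `ModelConfig.tiny`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .tokenizer import PAD, TokenizedWindow

# ---------------------------------------------------------------- config


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    n_layers: int = 12
    n_heads: int = 12
    d_model: int = 768
    d_ffn: int = 3072
    max_positions: int = 512
    dropout: float = 0.1
    layer_norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model = {self.d_model} not divisible by n_heads = {self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def tiny(cls, vocab_size: int, max_positions: int = 128, **kw) -> "ModelConfig":
        """Desk-scale configuration for CPU-sized experiments."""
        defaults = dict(
            n_layers=2, n_heads=2, d_model=32, d_ffn=64, max_positions=max_positions
        )
        defaults.update(kw)
        return cls(vocab_size=vocab_size, **defaults)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ------------------------------------------------------------- primitives


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return x * ndtr(x)


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return ndtr(x) + x * norm.pdf(x)


def _layer_norm(x, g, b, eps):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


# ------------------------------------------------------------------ init


_LAYER_MATS = ("Wq", "Wk", "Wv", "Wo", "W1", "W2")
_INIT_STD = 0.02


def init_params(config: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """Random initialization (normal, sd 0.02); deterministic given seed."""
    rng = np.random.default_rng(seed)
    d, f, V = config.d_model, config.d_ffn, config.vocab_size
    p: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0, _INIT_STD, (V, d)),
        "pos_emb": rng.normal(0, _INIT_STD, (config.max_positions, d)),
    }
    for i in range(config.n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"L{i}.{name}"] = rng.normal(0, _INIT_STD, (d, d))
            p[f"L{i}.b{name[1:].lower()}"] = np.zeros(d)
        p[f"L{i}.W1"] = rng.normal(0, _INIT_STD, (d, f))
        p[f"L{i}.b1"] = np.zeros(f)
        p[f"L{i}.W2"] = rng.normal(0, _INIT_STD, (f, d))
        p[f"L{i}.b2"] = np.zeros(d)
        p[f"L{i}.ln1_g"] = np.ones(d)
        p[f"L{i}.ln1_b"] = np.zeros(d)
        p[f"L{i}.ln2_g"] = np.ones(d)
        p[f"L{i}.ln2_b"] = np.zeros(d)
    p["mlm_W"] = rng.normal(0, _INIT_STD, (d, V))
    p["mlm_b"] = np.zeros(V)
    p["cls_W"] = rng.normal(0, _INIT_STD, (d, 2))
    p["cls_b"] = np.zeros(2)
    return p


# --------------------------------------------------------------- forward


def _dropout_mask(rng, shape, rate):
    return (rng.random(shape) >= rate) / (1.0 - rate)


def forward(
    params: dict,
    config: ModelConfig,
    ids: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Run the encoder on an id batch of shape (B, T).

    Returns (hidden, attn, cache): `hidden` is a list of length
    n_layers + 1 of (B, T, d) arrays (embedding output first), `attn` a
    list of (B, H, T, T) row-stochastic attention maps, and `cache` holds
    the intermediates the backward pass needs.
    """
    ids = np.atleast_2d(ids)
    B, T = ids.shape
    if T > config.max_positions:
        raise ValueError(f"window length {T} exceeds max_positions")
    H, dh = config.n_heads, config.d_head
    scale = 1.0 / np.sqrt(dh)
    drop = config.dropout if train else 0.0
    if drop > 0 and rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")

    pad_key = ids == PAD  # (B, T) keys excluded from every attention row

    emb = params["tok_emb"][ids] + params["pos_emb"][:T]
    emb_mask = _dropout_mask(rng, emb.shape, drop) if drop > 0 else None
    X = emb * emb_mask if emb_mask is not None else emb

    hidden = [X]
    attn_maps = []
    layer_caches = []
    for i in range(config.n_layers):
        pre = f"L{i}."
        Q = X @ params[pre + "Wq"] + params[pre + "bq"]
        K = X @ params[pre + "Wk"] + params[pre + "bk"]
        V = X @ params[pre + "Wv"] + params[pre + "bv"]
        Qh = Q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        Kh = K.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        Vh = V.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        scores = (Qh @ Kh.transpose(0, 1, 3, 2)) * scale
        scores = np.where(pad_key[:, None, None, :], -np.inf, scores)
        A = _softmax(scores, axis=-1)
        ctx = (A @ Vh).transpose(0, 2, 1, 3).reshape(B, T, config.d_model)
        O = ctx @ params[pre + "Wo"] + params[pre + "bo"]
        mask1 = _dropout_mask(rng, O.shape, drop) if drop > 0 else None
        if mask1 is not None:
            O = O * mask1
        X1, ln1c = _layer_norm(
            X + O, params[pre + "ln1_g"], params[pre + "ln1_b"], config.layer_norm_eps
        )
        Hpre = X1 @ params[pre + "W1"] + params[pre + "b1"]
        Hact = _gelu(Hpre)
        F = Hact @ params[pre + "W2"] + params[pre + "b2"]
        mask2 = _dropout_mask(rng, F.shape, drop) if drop > 0 else None
        if mask2 is not None:
            F = F * mask2
        X2, ln2c = _layer_norm(
            X1 + F, params[pre + "ln2_g"], params[pre + "ln2_b"], config.layer_norm_eps
        )
        layer_caches.append(
            dict(
                X=X, Qh=Qh, Kh=Kh, Vh=Vh, A=A, ctx=ctx,
                mask1=mask1, ln1c=ln1c, X1=X1, Hpre=Hpre, Hact=Hact,
                mask2=mask2, ln2c=ln2c,
            )
        )
        attn_maps.append(A)
        hidden.append(X2)
        X = X2

    cache = dict(ids=ids, emb_mask=emb_mask, layers=layer_caches)
    return hidden, attn_maps, cache


def backward(
    params: dict, config: ModelConfig, cache: dict, d_last: np.ndarray
) -> dict[str, np.ndarray]:
    """Backpropagate a gradient w.r.t. the final hidden states (B, T, d)."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    B, T = cache["ids"].shape
    H, dh = config.n_heads, config.d_head
    scale = 1.0 / np.sqrt(dh)
    dX = d_last
    for i in reversed(range(config.n_layers)):
        pre = f"L{i}."
        c = cache["layers"][i]
        dS2, dg2, db2 = _layer_norm_backward(dX, c["ln2c"])
        grads[pre + "ln2_g"] += dg2
        grads[pre + "ln2_b"] += db2
        dX1 = dS2.copy()
        dF = dS2 * c["mask2"] if c["mask2"] is not None else dS2
        grads[pre + "W2"] += np.einsum("btf,btd->fd", c["Hact"], dF)
        grads[pre + "b2"] += dF.sum(axis=(0, 1))
        dHact = dF @ params[pre + "W2"].T
        dHpre = dHact * _gelu_grad(c["Hpre"])
        grads[pre + "W1"] += np.einsum("btd,btf->df", c["X1"], dHpre)
        grads[pre + "b1"] += dHpre.sum(axis=(0, 1))
        dX1 += dHpre @ params[pre + "W1"].T

        dS1, dg1, db1 = _layer_norm_backward(dX1, c["ln1c"])
        grads[pre + "ln1_g"] += dg1
        grads[pre + "ln1_b"] += db1
        dX = dS1.copy()
        dO = dS1 * c["mask1"] if c["mask1"] is not None else dS1
        grads[pre + "Wo"] += np.einsum("btd,bte->de", c["ctx"], dO)
        grads[pre + "bo"] += dO.sum(axis=(0, 1))
        dctx = (dO @ params[pre + "Wo"].T).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        A, Vh = c["A"], c["Vh"]
        dA = dctx @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dctx
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dscores @ c["Kh"] * scale
        dKh = dscores.transpose(0, 1, 3, 2) @ c["Qh"] * scale
        dQ = dQh.transpose(0, 2, 1, 3).reshape(B, T, config.d_model)
        dK = dKh.transpose(0, 2, 1, 3).reshape(B, T, config.d_model)
        dV = dVh.transpose(0, 2, 1, 3).reshape(B, T, config.d_model)
        X = c["X"]
        for nm, dmat in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            grads[pre + nm] += np.einsum("btd,bte->de", X, dmat)
            grads[pre + "b" + nm[1:].lower()] += dmat.sum(axis=(0, 1))
            dX += dmat @ params[pre + nm].T

    if cache["emb_mask"] is not None:
        dX = dX * cache["emb_mask"]
    grads["pos_emb"][:T] += dX.sum(axis=0)
    flat_ids = cache["ids"].reshape(-1)
    np.add.at(grads["tok_emb"], flat_ids, dX.reshape(-1, config.d_model))
    return grads


# ----------------------------------------------------------- MLM loss


def mlm_loss_and_grads(
    params: dict,
    config: ModelConfig,
    corrupted: np.ndarray,
    targets: np.ndarray,
    loss_mask: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy of the true token over masked positions, with grads."""
    corrupted = np.atleast_2d(corrupted)
    targets = np.atleast_2d(targets)
    loss_mask = np.atleast_2d(loss_mask)
    hidden, _, cache = forward(params, config, corrupted, train=train, rng=rng)
    Xl = hidden[-1]
    rows = np.nonzero(loss_mask)
    M = rows[0].size
    if M == 0:
        warnings.warn("empty loss mask: MLM loss defined as 0", stacklevel=2)
        return 0.0, {k: np.zeros_like(v) for k, v in params.items()}
    x = Xl[rows]  # (M, d)
    logits = x @ params["mlm_W"] + params["mlm_b"]  # (M, V)
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    tgt = targets[rows]
    loss = float(-logp[np.arange(M), tgt].mean())

    dlogits = np.exp(logp)
    dlogits[np.arange(M), tgt] -= 1.0
    dlogits /= M
    dXl = np.zeros_like(Xl)
    dXl[rows] = dlogits @ params["mlm_W"].T
    grads = backward(params, config, cache, dXl)
    grads["mlm_W"] += x.T @ dlogits
    grads["mlm_b"] += dlogits.sum(axis=0)
    return loss, grads


def mlm_loss(params, config, corrupted, targets, loss_mask) -> float:
    """Evaluation-mode MLM loss (no gradients, no dropout)."""
    loss, _ = mlm_loss_and_grads(params, config, corrupted, targets, loss_mask)
    return loss


def mlm_predict(params, config, corrupted: np.ndarray) -> np.ndarray:
    """Argmax token ids at every position (B, T)."""
    hidden, _, _ = forward(params, config, np.atleast_2d(corrupted))
    logits = hidden[-1] @ params["mlm_W"] + params["mlm_b"]
    return logits.argmax(axis=-1)


# -------------------------------------------------------- task heads


def classify_batch(params, config, ids: np.ndarray) -> np.ndarray:
    """Positive-class probability for each window in an id batch."""
    hidden, _, _ = forward(params, config, np.atleast_2d(ids))
    logits = hidden[-1][:, 0, :] @ params["cls_W"] + params["cls_b"]
    return _softmax(logits, axis=-1)[:, 1]


def classify_window(params, config, window: TokenizedWindow) -> float:
    """Positive-class probability from the final-layer [CLS] vector."""
    return float(classify_batch(params, config, window.ids[None, :])[0])


def classification_loss_and_grads(
    params, config, ids: np.ndarray, labels: np.ndarray,
    train: bool = False, rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Binary cross-entropy on the 2-class [CLS] softmax, with grads."""
    ids = np.atleast_2d(ids)
    labels = np.asarray(labels, dtype=np.int64)
    hidden, _, cache = forward(params, config, ids, train=train, rng=rng)
    x_cls = hidden[-1][:, 0, :]
    logits = x_cls @ params["cls_W"] + params["cls_b"]
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    B = ids.shape[0]
    loss = float(-logp[np.arange(B), labels].mean())
    dlogits = np.exp(logp)
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    dXl = np.zeros_like(hidden[-1])
    dXl[:, 0, :] = dlogits @ params["cls_W"].T
    grads = backward(params, config, cache, dXl)
    grads["cls_W"] += x_cls.T @ dlogits
    grads["cls_b"] += dlogits.sum(axis=0)
    return loss, grads


@dataclass
class EncoderState:
    """Per-layer hidden states and attention maps for one window."""

    hidden: list[np.ndarray]  # each (T, d)
    attention: list[np.ndarray]  # each (H, T, T)
    n_real_tokens: int
    ids: np.ndarray


def encode_window(params, config, window: TokenizedWindow) -> EncoderState:
    """Evaluation-mode forward pass retaining all attention maps."""
    hidden, attn, _ = forward(params, config, window.ids[None, :])
    return EncoderState(
        hidden=[h[0] for h in hidden],
        attention=[a[0] for a in attn],
        n_real_tokens=window.n_real_tokens,
        ids=window.ids,
    )


def embed_long_sequence(
    params, config, windows: list[TokenizedWindow]
) -> np.ndarray:
    """Frozen-encoder embedding of a long sequence.

    Final-layer hidden states are mean-pooled over the real token positions
    of each window, then averaged across windows, yielding one d-vector.
    """
    if not windows:
        raise ValueError("no windows to embed")
    pooled = []
    for w in windows:
        hidden, _, _ = forward(params, config, w.ids[None, :])
        pooled.append(hidden[-1][0, w.real_slice, :].mean(axis=0))
    return np.mean(pooled, axis=0)


class MultiLabelHead:
    """Independent sigmoid per compartment on frozen embeddings.

    Labels are not mutually exclusive; calls use a 0.5 threshold. Trained
    full-batch with Adam on the mean binary cross-entropy plus an L2 term.
    """

    LABELS = ("nucleus", "exosome", "cytosol", "ribosome", "membrane", "ER")

    def __init__(self, d: int, n_labels: int = 6, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0, _INIT_STD, (d, n_labels))
        self.b = np.zeros(n_labels)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(X) @ self.W + self.b
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def fit(
        self, X: np.ndarray, Y: np.ndarray,
        lr: float = 0.05, n_iter: int = 500, l2: float = 1e-4,
    ) -> "MultiLabelHead":
        X = np.atleast_2d(X)
        Y = np.asarray(Y, dtype=float)
        mW = np.zeros_like(self.W); vW = np.zeros_like(self.W)
        mb = np.zeros_like(self.b); vb = np.zeros_like(self.b)
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        for t in range(1, n_iter + 1):
            P = self.predict_proba(X)
            dZ = (P - Y) / n
            gW = X.T @ dZ + l2 * self.W
            gb = dZ.sum(axis=0)
            mW = b1 * mW + (1 - b1) * gW; vW = b2 * vW + (1 - b2) * gW**2
            mb = b1 * mb + (1 - b1) * gb; vb = b2 * vb + (1 - b2) * gb**2
            c1, c2 = 1 - b1**t, 1 - b2**t
            self.W -= lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
            self.b -= lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
        return self


# ----------------------------------------------------------- checkpoints


def save_checkpoint(directory: str | Path, params: dict, config: ModelConfig) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **params)
    (directory / "config.json").write_text(json.dumps(config.to_dict(), indent=2))


def load_checkpoint(directory: str | Path) -> tuple[dict, ModelConfig]:
    directory = Path(directory)
    config = ModelConfig.from_dict(json.loads((directory / "config.json").read_text()))
    with np.load(directory / "params.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return params, config
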