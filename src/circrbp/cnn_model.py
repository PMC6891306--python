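"""Three-branch convolutional classifier for fixed-length one-hot sequences.

Architecture: for each kernel size h in (by default) {8, 20, 38}, a bank of
kernels (4xh weight matrices) is slid over the one-hot input with valid
padding and ReLU activation, producing feature maps of length L-h+1; each
feature map is reduced by global max-pooling to a single value; the pooled
values from all branches are concatenated, passed through dropout, and a
dense layer with two-unit softmax yields the class probability pair.
Training minimizes cross-entropy with Adam, mini-batches reshuffled per
epoch, and early stopping on validation accuracy (best-epoch weights kept).

The network, its gradients and the Adam optimizer are implemented directly
on NumPy arrays; with a fixed seed every run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from circrbp._rng import substream
from circrbp.encoding import encode_records, encode_unlabeled, one_hot_encode
from circrbp.sequence_io import DatasetSplit, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults follow the full-scale setting (1024 kernels per size, batch 512,
    up to 50 epochs); tests and desk-scale experiments pass smaller values.
    """

    kernel_sizes: list[int] = field(default_factory=lambda: [8, 20, 38])
    kernels_per_size: int = 1024
    dropout_rate: float = 0.5
    batch_size: int = 512
    max_epochs: int = 50
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0

    def validate(self, L: Optional[int] = None) -> None:
        if self.kernels_per_size < 1:
            raise ValueError("kernels_per_size must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(h < 1 for h in self.kernel_sizes):
            raise ValueError("kernel sizes must be positive")
        if L is not None and any(h > L for h in self.kernel_sizes):
            raise ValueError(f"kernel size exceeds input length {L}")


@dataclass
class TrainedModel:
    """Weights of the three-branch network plus its config and history."""

    config: ModelConfig
    L: int
    conv_weights: list[np.ndarray]   # per branch: (kernels_per_size, 4, h)
    conv_biases: list[np.ndarray]    # per branch: (kernels_per_size,)
    dense_weight: np.ndarray         # (n_branches * kernels_per_size, 2)
    dense_bias: np.ndarray           # (2,)
    training_history: list[dict] = field(default_factory=list)

    @property
    def n_kernels(self) -> int:
        return len(self.conv_weights) * self.config.kernels_per_size

    def kernel(self, kernel_id: int) -> tuple[np.ndarray, float, int]:
        """Return (weight 4xh, bias, kernel size) for a global kernel index.

        Kernels are numbered 0 .. n_kernels-1 across branches in kernel-size
        order (all size-8 kernels first, then size-20, then size-38).
        """
        if not (0 <= kernel_id < self.n_kernels):
            raise IndexError(f"kernel_id {kernel_id} out of range [0, {self.n_kernels})")
        nk = self.config.kernels_per_size
        branch, idx = divmod(kernel_id, nk)
        return (
            self.conv_weights[branch][idx],
            float(self.conv_biases[branch][idx]),
            self.config.kernel_sizes[branch],
        )

    def save(self, path: str | Path) -> None:
        """Write a single checkpoint archive: JSON config + weight tensors."""
        arrays = {"dense_weight": self.dense_weight, "dense_bias": self.dense_bias}
        for i, (w, b) in enumerate(zip(self.conv_weights, self.conv_biases)):
            arrays[f"conv_w_{i}"] = w
            arrays[f"conv_b_{i}"] = b
        meta = {"config": asdict(self.config), "L": self.L, "history": self.training_history}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            config = ModelConfig(**meta["config"])
            n_branches = len(config.kernel_sizes)
            return cls(
                config=config,
                L=meta["L"],
                conv_weights=[data[f"conv_w_{i}"] for i in range(n_branches)],
                conv_biases=[data[f"conv_b_{i}"] for i in range(n_branches)],
                dense_weight=data["dense_weight"],
                dense_bias=data["dense_bias"],
                training_history=meta["history"],
            )


def build_model(config: ModelConfig, L: int) -> TrainedModel:
    """Initialize an untrained model with seeded Glorot-uniform weights."""
    config.validate(L)
    rng = substream(config.seed, "init")
    conv_w, conv_b = [], []
    nk = config.kernels_per_size
    for h in config.kernel_sizes:
        limit = np.sqrt(6.0 / (4 * h + nk))
        conv_w.append(rng.uniform(-limit, limit, size=(nk, 4, h)))
        conv_b.append(np.zeros(nk))
    n_feat = len(config.kernel_sizes) * nk
    limit = np.sqrt(6.0 / (n_feat + 2))
    dense_w = rng.uniform(-limit, limit, size=(n_feat, 2))
    return TrainedModel(
        config=config,
        L=L,
        conv_weights=conv_w,
        conv_biases=conv_b,
        dense_weight=dense_w,
        dense_bias=np.zeros(2),
    )


def conv_forward(M: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """ReLU convolution of one kernel over one one-hot matrix (valid padding).

    Returns the feature map c with c_i = max(0, sum(w * M[:, i:i+h]) + b),
    of length L - h + 1.
    """
    M = np.asarray(M, dtype=float)
    w = np.asarray(w, dtype=float)
    if M.ndim != 2 or M.shape[0] != 4 or w.ndim != 2 or w.shape[0] != 4:
        raise ValueError(f"shape mismatch: M {M.shape}, w {w.shape}")
    h = w.shape[1]
    L = M.shape[1]
    if h > L:
        raise ValueError(f"kernel width {h} exceeds sequence length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(M, h, axis=1)  # (4, L-h+1, h)
    z = np.einsum("rph,rh->p", windows, w) + b
    return np.maximum(z, 0.0)


def global_max_pool(c: np.ndarray) -> float:
    """Reduce a feature map to its maximum activation."""
    c = np.asarray(c)
    if c.size == 0:
        raise ValueError("empty feature map")
    return float(c.max())


def _branch_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Vectorized branch pass. X (N,4,L), W (nk,4,h) -> pooled (N,nk), caches."""
    h = W.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(X, h, axis=2)   # (N,4,P,h)
    win = np.ascontiguousarray(win.transpose(0, 2, 1, 3))          # (N,P,4,h)
    N, P = win.shape[0], win.shape[1]
    flat = win.reshape(N, P, 4 * h)
    z = flat @ W.reshape(W.shape[0], -1).T + b                     # (N,P,nk)
    a = np.maximum(z, 0.0)
    pooled = a.max(axis=1)                                         # (N,nk)
    argmax = a.argmax(axis=1)                                      # (N,nk)
    return pooled, argmax, flat


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_batch(model: TrainedModel, X: np.ndarray, dropout_mask: Optional[np.ndarray] = None):
    pooled_parts, caches = [], []
    for W, b in zip(model.conv_weights, model.conv_biases):
        pooled, argmax, flat = _branch_forward(X, W, b)
        pooled_parts.append(pooled)
        caches.append((argmax, flat))
    feat = np.concatenate(pooled_parts, axis=1)  # (N, n_branches*nk)
    if dropout_mask is not None:
        feat = feat * dropout_mask
    logits = feat @ model.dense_weight + model.dense_bias
    return _softmax(logits), feat, caches


def forward(model: TrainedModel, M: np.ndarray) -> np.ndarray:
    """Probability pair (negative, positive) for one one-hot matrix."""
    M = np.asarray(M, dtype=float)
    if M.shape != (4, model.L):
        raise ValueError(f"expected input shape (4, {model.L}), got {M.shape}")
    probs, _, _ = _forward_batch(model, M[None, :, :])
    return probs[0]


def predict_proba(model: TrainedModel, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Positive-class probability for a batch of one-hot matrices (N,4,L)."""
    if X.shape[1:] != (4, model.L):
        raise ValueError(f"expected inputs of shape (4, {model.L}), got {X.shape[1:]}")
    out = np.empty(X.shape[0])
    for i in range(0, X.shape[0], batch_size):
        probs, _, _ = _forward_batch(model, X[i : i + batch_size])
        out[i : i + batch_size] = probs[:, 1]
    return out


def predict(model: TrainedModel, records: Sequence[SequenceRecord]) -> np.ndarray:
    """Positive-class probability per record, order preserved."""
    for r in records:
        if len(r) != model.L:
            raise ValueError(f"record {r.id!r} has length {len(r)}, model expects {model.L}")
    X, _ = encode_unlabeled(records)
    return predict_proba(model, X)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_grads(model: TrainedModel, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Cross-entropy loss and gradients for one mini-batch (dropout active)."""
    N = X.shape[0]
    n_feat = model.dense_weight.shape[0]
    p_drop = model.config.dropout_rate
    if p_drop > 0:
        mask = (rng.random((N, n_feat)) >= p_drop) / (1.0 - p_drop)
    else:
        mask = None
    probs, feat, caches = _forward_batch(model, X, dropout_mask=mask)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(N), y] + eps))
    onehot = np.zeros_like(probs)
    onehot[np.arange(N), y] = 1.0
    dlogits = (probs - onehot) / N                      # (N,2)
    dW_dense = feat.T @ dlogits
    db_dense = dlogits.sum(axis=0)
    dfeat = dlogits @ model.dense_weight.T              # (N,n_feat)
    if mask is not None:
        dfeat = dfeat * mask
    grads_w, grads_b = [], []
    nk = model.config.kernels_per_size
    for br, (argmax, flat) in enumerate(caches):
        g = dfeat[:, br * nk : (br + 1) * nk].copy()    # (N,nk)
        # pooled value 0 means the max pre-ReLU response was <= 0: no gradient
        pooled = flat[np.arange(N)[:, None], argmax]    # (N,nk,4h) gathered windows
        W = model.conv_weights[br]
        z_at_max = np.einsum("nkd,kd->nk", pooled, W.reshape(W.shape[0], -1)) + model.conv_biases[br]
        g[z_at_max <= 0] = 0.0
        dW = np.einsum("nk,nkd->kd", g, pooled).reshape(W.shape)
        grads_w.append(dW)
        grads_b.append(g.sum(axis=0))
    return loss, (grads_w, grads_b, dW_dense, db_dense)


def _accuracy(model: TrainedModel, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    scores = predict_proba(model, X, batch_size=batch_size)
    return float(np.mean((scores >= 0.5).astype(int) == y))


def train(
    model: TrainedModel,
    split: DatasetSplit,
    config: Optional[ModelConfig] = None,
) -> TrainedModel:
    """Train with Adam + cross-entropy, early-stopping on validation accuracy.

    Batches are reshuffled each epoch from the seeded stream. Training stops
    at max_epochs or when validation accuracy has not improved for `patience`
    epochs; the returned model carries the weights of the best-validation
    epoch and the full per-epoch history.
    """
    cfg = config if config is not None else model.config
    if not split.train or not split.validation:
        raise ValueError("train and validation partitions must be non-empty")
    X_tr, y_tr, _ = encode_records(split.train)
    X_va, y_va, _ = encode_records(split.validation)
    if X_tr.shape[2] != model.L:
        raise ValueError(f"training sequences of length {X_tr.shape[2]}, model expects {model.L}")

    rng = substream(cfg.seed, "train")
    params = model.conv_weights + model.conv_biases + [model.dense_weight, model.dense_bias]
    opt = _Adam(params, cfg.learning_rate)
    n_branches = len(model.conv_weights)

    best_acc, best_epoch = -np.inf, -1
    best_weights = None
    history: list[dict] = []
    N = X_tr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(N)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, N, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss, (gw, gb, gdw, gdb) = _loss_and_grads(model, X_tr[idx], y_tr[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss {loss} at epoch {epoch}, batch {n_batches}")
            opt.step(params, gw + gb + [gdw, gdb])
            epoch_loss += loss
            n_batches += 1
        train_acc = _accuracy(model, X_tr, y_tr, cfg.batch_size)
        val_acc = _accuracy(model, X_va, y_va, cfg.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        logger.info("epoch %d: loss %.4f train_acc %.4f val_acc %.4f", epoch, epoch_loss / max(n_batches, 1), train_acc, val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = (
                [w.copy() for w in model.conv_weights],
                [b.copy() for b in model.conv_biases],
                model.dense_weight.copy(),
                model.dense_bias.copy(),
            )
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best epoch %d, val_acc %.4f)", epoch, best_epoch, best_acc)
            break
    if best_weights is not None:
        model.conv_weights = best_weights[0]
        model.conv_biases = best_weights[1]
        model.dense_weight = best_weights[2]
        model.dense_bias = best_weights[3]
    model.training_history = history
    return model
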