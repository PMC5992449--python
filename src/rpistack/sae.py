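"""Stacked sparse auto-encoder for unsupervised feature learning.

Each layer is an auto-encoder ``h = f(x W + b)`` trained greedily (layer by
layer) to reconstruct its own input through a linear decoder, minimising a
squared reconstruction error plus an L1 sparsity penalty on the hidden
activations, ``L = ||x_hat - x||^2 + lambda * sum_j |h_j|``.  The hidden
activations of one trained layer become the training input of the next;
the deepest hidden activations are the learned feature representation.

An optional supervised fine-tuning phase appends a 2-class soft-max head,
switches the deepest hidden layer to ReLU, and updates every parameter by
SGD with momentum on the cross-entropy, applying dropout to hidden
activations during training only.  Pretraining uses Adam on the
reconstruction objective; both phases are deterministic under a fixed seed.

The implementation is plain NumPy: the networks here are small (a few
hundred units) and CPU-bound mini-batch gradient descent is entirely
adequate.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, softmax


def sigmoid(z):
    """Logistic activation 1 / (1 + e^(-z)), overflow-safe for any finite z."""
    return expit(z)


def relu(z):
    return np.maximum(z, 0.0)


_ACTIVATIONS = {"sigmoid": sigmoid, "relu": relu}


@dataclass
class TrainConfig:
    """Hyper-parameters for pretraining and fine-tuning.

    ``hidden_dims`` sets the stack architecture; ``adam_lr`` drives the
    per-layer reconstruction phase, ``sgd_lr``/``momentum`` the supervised
    fine-tuning phase.  ``sparsity_lambda`` weights the L1 penalty on hidden
    activations, ``dropout_p`` the fine-tuning dropout rate, and
    ``denoise_p`` an optional input-masking corruption during pretraining
    (off by default).
    """

    hidden_dims: Sequence[int] = (256, 128)
    batch_size: int = 100
    epochs: int = 100
    adam_lr: float = 1e-3
    sgd_lr: float = 0.01
    momentum: float = 0.9
    sparsity_lambda: float = 1e-4
    dropout_p: float = 0.5
    denoise_p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be positive integers")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")


@dataclass
class AutoEncoderLayer:
    """One encoder layer: weights, bias, activation and sparsity setting."""

    W: np.ndarray  # input_dim x hidden_dim
    b: np.ndarray  # hidden_dim
    activation: str = "sigmoid"
    sparsity_lambda: float = 0.0
    dropout_p: float = 0.5

    def forward(self, X: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation](X @ self.W + self.b)


@dataclass
class StackedAutoEncoder:
    """An ordered stack of encoder layers, optionally with a soft-max head."""

    layers: list[AutoEncoderLayer]
    fine_tuned: bool = False
    softmax_W: Optional[np.ndarray] = None
    softmax_b: Optional[np.ndarray] = None
    pretrain_losses: list[list[float]] = field(default_factory=list)
    fine_tune_losses: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.layers[0].W.shape[0]

    @property
    def output_dim(self) -> int:
        return self.layers[-1].W.shape[1]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist as a .npz of arrays plus an embedded JSON manifest."""
        arrays = {}
        meta = {
            "fine_tuned": self.fine_tuned,
            "n_layers": len(self.layers),
            "activations": [l.activation for l in self.layers],
            "sparsity_lambda": [l.sparsity_lambda for l in self.layers],
            "dropout_p": [l.dropout_p for l in self.layers],
        }
        for i, l in enumerate(self.layers):
            arrays[f"W{i}"] = l.W
            arrays[f"b{i}"] = l.b
        if self.softmax_W is not None:
            arrays["softmax_W"] = self.softmax_W
            arrays["softmax_b"] = self.softmax_b
        np.savez(path, manifest=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "StackedAutoEncoder":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["manifest"]))
            layers = [
                AutoEncoderLayer(
                    W=data[f"W{i}"],
                    b=data[f"b{i}"],
                    activation=meta["activations"][i],
                    sparsity_lambda=meta["sparsity_lambda"][i],
                    dropout_p=meta["dropout_p"][i],
                )
                for i in range(meta["n_layers"])
            ]
            sm_W = data["softmax_W"] if "softmax_W" in data else None
            sm_b = data["softmax_b"] if "softmax_b" in data else None
        return cls(
            layers=layers,
            fine_tuned=meta["fine_tuned"],
            softmax_W=sm_W,
            softmax_b=sm_b,
        )


def ae_loss(X: np.ndarray, X_hat: np.ndarray, H: np.ndarray, lam: float) -> float:
    """Mean per-sample reconstruction loss: ||x_hat - x||^2 + lam * sum|h|."""
    sq = np.sum((X_hat - X) ** 2, axis=1)
    l1 = lam * np.sum(np.abs(H), axis=1)
    return float(np.mean(sq + l1))


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    return X


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _train_ae_layer(
    X: np.ndarray, hidden_dim: int, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[AutoEncoderLayer, list[float]]:
    """Train one auto-encoder layer with Adam on the sparse reconstruction loss."""
    n, d = X.shape
    lam = cfg.sparsity_lambda
    scale = np.sqrt(1.0 / d)
    W1 = rng.normal(0.0, scale, size=(d, hidden_dim))
    b1 = np.zeros(hidden_dim)
    W2 = rng.normal(0.0, np.sqrt(1.0 / hidden_dim), size=(hidden_dim, d))
    b2 = np.zeros(d)
    params = [W1, b1, W2, b2]
    opt = _Adam(params, cfg.adam_lr)
    epoch_losses: list[float] = []
    for _ in range(cfg.epochs):
        total, count = 0.0, 0
        for idx in _batches(n, cfg.batch_size, rng):
            xb = X[idx]
            x_in = xb
            if cfg.denoise_p > 0.0:
                keep = rng.random(xb.shape) >= cfg.denoise_p
                x_in = xb * keep
            Z = x_in @ W1 + b1
            H = sigmoid(Z)
            X_hat = H @ W2 + b2
            B = xb.shape[0]
            total += ae_loss(xb, X_hat, H, lam) * B
            count += B
            # gradients of mean-over-batch loss
            dXh = 2.0 * (X_hat - xb) / B
            gW2 = H.T @ dXh
            gb2 = dXh.sum(axis=0)
            dH = dXh @ W2.T + lam * np.sign(H) / B
            dZ = dH * H * (1.0 - H)
            gW1 = x_in.T @ dZ
            gb1 = dZ.sum(axis=0)
            opt.step(params, [gW1, gb1, gW2, gb2])
        epoch_losses.append(total / count)
    layer = AutoEncoderLayer(
        W=W1, b=b1, activation="sigmoid",
        sparsity_lambda=lam, dropout_p=cfg.dropout_p,
    )
    return layer, epoch_losses


def pretrain(X: np.ndarray, cfg: TrainConfig) -> StackedAutoEncoder:
    """Greedy layer-wise pretraining of the full stack on unlabelled data."""
    X = _check_finite(X)
    rng = np.random.default_rng(cfg.seed)
    layers: list[AutoEncoderLayer] = []
    losses: list[list[float]] = []
    current = X
    for hidden_dim in cfg.hidden_dims:
        layer, epoch_losses = _train_ae_layer(current, hidden_dim, cfg, rng)
        layers.append(layer)
        losses.append(epoch_losses)
        current = layer.forward(current)
    return StackedAutoEncoder(layers=layers, pretrain_losses=losses)


def transform(model: StackedAutoEncoder, X: np.ndarray) -> np.ndarray:
    """Deepest hidden activations for X (deterministic, no dropout)."""
    X = _check_finite(X)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} columns, model expects {model.input_dim}"
        )
    H = X
    for layer in model.layers:
        H = layer.forward(H)
    return H


def predict_proba(model: StackedAutoEncoder, X: np.ndarray) -> np.ndarray:
    """Class probabilities from the soft-max head of a fine-tuned model."""
    if not model.fine_tuned or model.softmax_W is None:
        raise ValueError("model has no soft-max head; call fine_tune first")
    H = transform(model, X)
    return softmax(H @ model.softmax_W + model.softmax_b, axis=1)


def fine_tune(
    model: StackedAutoEncoder, X: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> StackedAutoEncoder:
    """Supervised fine-tuning through an appended 2-class soft-max head.

    Returns a new model (the pretrained input is left untouched): the deepest
    hidden layer switches to ReLU, dropout is applied to hidden activations
    during training, and all parameters are updated by SGD with momentum on
    the cross-entropy loss.
    """
    X = _check_finite(X)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("fine_tune requires both classes present in y")
    model = copy.deepcopy(model)
    model.layers[-1].activation = "relu"
    rng = np.random.default_rng(cfg.seed + 1)
    h = model.output_dim
    sm_W = rng.normal(0.0, np.sqrt(1.0 / h), size=(h, 2))
    sm_b = np.zeros(2)
    params = [p for l in model.layers for p in (l.W, l.b)] + [sm_W, sm_b]
    velocity = [np.zeros_like(p) for p in params]
    Y = np.eye(2)[y]
    n = X.shape[0]
    p_drop = cfg.dropout_p
    epoch_losses: list[float] = []
    for _ in range(cfg.epochs):
        total, count = 0.0, 0
        for idx in _batches(n, cfg.batch_size, rng):
            xb, yb = X[idx], Y[idx]
            B = xb.shape[0]
            # forward with inverted dropout on hidden activations
            acts = [xb]
            preacts = []
            masks = []
            H = xb
            for layer in model.layers:
                Z = H @ layer.W + layer.b
                H = _ACTIVATIONS[layer.activation](Z)
                if p_drop > 0.0:
                    mask = (rng.random(H.shape) >= p_drop) / (1.0 - p_drop)
                    H = H * mask
                else:
                    mask = np.ones_like(H)
                preacts.append(Z)
                masks.append(mask)
                acts.append(H)
            logits = H @ sm_W + sm_b
            P = softmax(logits, axis=1)
            eps = 1e-12
            total += float(-np.sum(yb * np.log(P + eps)))
            count += B
            # backward
            dlogits = (P - yb) / B
            grads = [None] * len(params)
            grads[-2] = acts[-1].T @ dlogits
            grads[-1] = dlogits.sum(axis=0)
            dH = dlogits @ sm_W.T
            for li in range(len(model.layers) - 1, -1, -1):
                layer = model.layers[li]
                dH = dH * masks[li]
                if layer.activation == "sigmoid":
                    A = _ACTIVATIONS["sigmoid"](preacts[li])
                    dZ = dH * A * (1.0 - A)
                else:  # relu
                    dZ = dH * (preacts[li] > 0.0)
                grads[2 * li] = acts[li].T @ dZ
                grads[2 * li + 1] = dZ.sum(axis=0)
                dH = dZ @ layer.W.T
            for p, g, v in zip(params, grads, velocity):
                v *= cfg.momentum
                v -= cfg.sgd_lr * g
                p += v
        epoch_losses.append(total / count)
    model.fine_tuned = True
    model.softmax_W = sm_W
    model.softmax_b = sm_b
    model.fine_tune_losses = epoch_losses
    return model
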