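"""Fully connected network with hand-written backprop, SGD and Adam.

The forward map is Z_l = W_l A_{l-1} + b_l with ReLU hidden activations and
a linear output; the loss is the mean over samples of the squared error
vector norm; Adam keeps exponentially decayed first/second gradient moments
with bias correction. These primitives are the core of the inverse-model
identification, so they are implemented directly rather than delegated to a
learning framework. :class:`FCNNRegressor` wraps them in a scikit-learn
style estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "NetworkParams",
    "ForwardCache",
    "Gradients",
    "AdamState",
    "TrainConfig",
    "TrainingDivergedError",
    "init_network",
    "forward",
    "mse_loss",
    "backward",
    "sgd_update",
    "adam_step",
    "train",
    "FCNNRegressor",
]


@dataclass
class NetworkParams:
    """Layer weights W_l (d_l x d_{l-1}) and biases b_l (d_l,)."""

    weights: list
    biases: list

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("need one bias vector per weight matrix")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape[0] != b.shape[0]:
                raise ValueError(f"layer {l}: weight rows {W.shape[0]} != bias length {b.shape[0]}")
            if l > 0 and W.shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(f"layer {l}: input width {W.shape[1]} breaks the shape chain")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def layer_dims(self) -> tuple:
        return (self.weights[0].shape[1],) + tuple(W.shape[0] for W in self.weights)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "NetworkParams":
        return NetworkParams([W.copy() for W in self.weights], [b.copy() for b in self.biases])


@dataclass
class ForwardCache:
    """Pre-activations Z_l and activations A_l kept for backprop (columns = samples)."""

    Z: list
    A: list  # A[0] is the input


@dataclass
class Gradients:
    dW: list
    db: list


def init_network(layer_dims: Sequence[int], seed: int = 0) -> NetworkParams:
    """He-scaled Gaussian weights (std sqrt(2/fan_in)), zero biases; deterministic per seed."""
    dims = [int(d) for d in layer_dims]
    if len(dims) < 2 or any(d < 1 for d in dims):
        raise ValueError(f"layer_dims must list >= 2 positive widths, got {layer_dims}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_out, d_in)))
        biases.append(np.zeros(d_out))
    return NetworkParams(weights, biases)


def forward(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, ForwardCache]:
    """Propagate samples (rows of X) through the network.

    Hidden layers apply ReLU f(x)=max(0,x); the output layer is linear
    (regression). Returns predictions of shape (m, d_L) and the cache.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d0 = params.weights[0].shape[1]
    if X.shape[1] != d0:
        raise ValueError(f"expected {d0} input features, got {X.shape[1]}")
    A = X.T  # (d0, m)
    cache = ForwardCache(Z=[], A=[A])
    L = params.n_layers
    for l, (W, b) in enumerate(zip(params.weights, params.biases)):
        Z = W @ A + b[:, None]
        A = np.maximum(Z, 0.0) if l < L - 1 else Z
        cache.Z.append(Z)
        cache.A.append(A)
    return A.T, cache


def mse_loss(Y_hat: np.ndarray, Y: np.ndarray) -> float:
    """Mean over samples of the squared error norm: (1/m) sum_i ||yhat_i - y_i||^2."""
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y_hat.shape != Y.shape:
        raise ValueError(f"shape mismatch: {Y_hat.shape} vs {Y.shape}")
    m = Y_hat.shape[0]
    if m < 1:
        raise ValueError("need at least one sample")
    return float(np.sum((Y_hat - Y) ** 2) / m)


def backward(params: NetworkParams, cache: ForwardCache, Y: np.ndarray) -> Gradients:
    """Exact gradients of the MSE loss through the ReLU/linear chain.

    The ReLU subgradient at exactly 0 is taken as 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = params.n_layers
    A_L = cache.A[-1]  # (d_L, m)
    if A_L.shape != Y.T.shape:
        raise ValueError(f"stale cache: output shape {A_L.shape} vs targets {Y.T.shape}")
    m = Y.shape[0]
    dA = 2.0 * (A_L - Y.T) / m
    dW = [None] * L
    db = [None] * L
    for l in range(L - 1, -1, -1):
        dZ = dA if l == L - 1 else dA * (cache.Z[l] > 0)
        dW[l] = dZ @ cache.A[l].T
        db[l] = dZ.sum(axis=1)
        if l > 0:
            dA = params.weights[l].T @ dZ
    return Gradients(dW=dW, db=db)


def sgd_update(params: NetworkParams, grads: Gradients, lam: float) -> NetworkParams:
    """Plain gradient-descent step theta <- theta - lam * grad."""
    return NetworkParams(
        [W - lam * g for W, g in zip(params.weights, grads.dW)],
        [b - lam * g for b, g in zip(params.biases, grads.db)],
    )


@dataclass
class AdamState:
    """Per-parameter first/second moment estimates and the step counter."""

    m_w: list
    v_w: list
    m_b: list
    v_b: list
    t: int = 0
    lam: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("decay rates beta1, beta2 must lie in [0, 1)")

    @classmethod
    def init(cls, params: NetworkParams, lam: float = 1e-3, beta1: float = 0.9,
             beta2: float = 0.999, eps: float = 1e-8) -> "AdamState":
        return cls(
            m_w=[np.zeros_like(W) for W in params.weights],
            v_w=[np.zeros_like(W) for W in params.weights],
            m_b=[np.zeros_like(b) for b in params.biases],
            v_b=[np.zeros_like(b) for b in params.biases],
            t=0, lam=lam, beta1=beta1, beta2=beta2, eps=eps,
        )


def adam_step(params: NetworkParams, grads: Gradients, state: AdamState) -> tuple[NetworkParams, AdamState]:
    """One Adam update.

    m_t = b1 m_{t-1} + (1-b1) g;  v_t = b2 v_{t-1} + (1-b2) g^2;
    bias-corrected mhat = m_t/(1-b1^t), vhat = v_t/(1-b2^t);
    theta <- theta - lam * mhat / (sqrt(vhat) + eps). The step counter is
    incremented before the corrections.
    """
    state.t += 1
    t, b1, b2 = state.t, state.beta1, state.beta2
    c1, c2 = 1.0 - b1**t, 1.0 - b2**t
    new_w, new_b = [], []
    for l in range(params.n_layers):
        for (theta, g, m, v, out) in (
            (params.weights[l], grads.dW[l], state.m_w, state.v_w, new_w),
            (params.biases[l], grads.db[l], state.m_b, state.v_b, new_b),
        ):
            m[l] = b1 * m[l] + (1.0 - b1) * g
            v[l] = b2 * v[l] + (1.0 - b2) * g * g
            m_hat = m[l] / c1
            v_hat = v[l] / c2
            out.append(theta - state.lam * m_hat / (np.sqrt(v_hat) + state.eps))
    return NetworkParams(new_w, new_b), state


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, lam: float):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch} with learning rate {lam}")
        self.epoch = epoch
        self.lam = lam


@dataclass
class TrainConfig:
    """Full-batch training settings."""

    max_epochs: int = 2000
    lam: float = 1e-3
    optimizer: str = "adam"      # "adam" | "sgd"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    val_fraction: float = 0.0    # chronological tail held out for early stopping
    patience: int | None = None  # epochs without val improvement before stopping

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def train(
    X: np.ndarray,
    Y: np.ndarray,
    layer_dims: Sequence[int],
    cfg: TrainConfig,
    init_params: NetworkParams | None = None,
) -> tuple[NetworkParams, dict]:
    """Minimize the MSE loss by full-batch SGD or Adam.

    Returns the best parameters (best validation loss when a validation
    split is configured, else the final parameters) and a history dict with
    per-epoch train (and val) losses. Deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    n_val = int(round(cfg.val_fraction * X.shape[0]))
    if cfg.patience is not None and n_val == 0:
        raise ValueError("early stopping requires a validation split (val_fraction > 0)")
    X_tr, Y_tr = (X[:-n_val], Y[:-n_val]) if n_val else (X, Y)
    X_val, Y_val = (X[-n_val:], Y[-n_val:]) if n_val else (None, None)

    params = init_params.copy() if init_params is not None else init_network(layer_dims, seed=cfg.seed)
    adam = AdamState.init(params, lam=cfg.lam, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    history: dict = {"train_loss": [], "val_loss": []}
    best_params, best_val, stale = params.copy(), np.inf, 0
    for epoch in range(cfg.max_epochs):
        Y_hat, cache = forward(params, X_tr)
        loss = mse_loss(Y_hat, Y_tr)
        if not math.isfinite(loss):
            raise TrainingDivergedError(epoch, cfg.lam)
        grads = backward(params, cache, Y_tr)
        if cfg.optimizer == "adam":
            params, adam = adam_step(params, grads, adam)
        else:
            params = sgd_update(params, grads, cfg.lam)
        history["train_loss"].append(loss)
        if n_val:
            val_loss = mse_loss(forward(params, X_val)[0], Y_val)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val, best_params, stale = val_loss, params.copy(), 0
            else:
                stale += 1
                if cfg.patience is not None and stale > cfg.patience:
                    break
    if n_val:
        return best_params, history
    return params, history


class FCNNRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style regressor over the hand-written FCNN/Adam core.

    Parameters follow the usual estimator conventions; fitted state lives in
    trailing-underscore attributes (``network_params_``, ``loss_history_``).
    """

    def __init__(
        self,
        hidden_layer_sizes=(32, 16),
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        max_epochs: int = 2000,
        validation_fraction: float = 0.0,
        patience: int | None = None,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    def _train_cfg(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            lam=self.learning_rate,
            optimizer=self.optimizer,
            beta1=self.beta1,
            beta2=self.beta2,
            eps=self.eps,
            seed=self.random_state,
            val_fraction=self.validation_fraction,
            patience=self.patience,
        )

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        y2 = y[:, None] if y.ndim == 1 else y
        if X.shape[0] != y2.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        dims = [X.shape[1], *self.hidden_layer_sizes, y2.shape[1]]
        self.network_params_, history = train(X, y2, dims, self._train_cfg())
        self.loss_history_ = history["train_loss"]
        self.val_loss_history_ = history["val_loss"]
        self.n_features_in_ = X.shape[1]
        self._y_1d = y.ndim == 1
        return self

    def predict(self, X):
        if not hasattr(self, "network_params_"):
            raise RuntimeError("estimator is not fitted")
        Y_hat, _ = forward(self.network_params_, np.atleast_2d(np.asarray(X, dtype=float)))
        return Y_hat[:, 0] if self._y_1d else Y_hat
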