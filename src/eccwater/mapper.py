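"""Neural-network cost surrogate ("mapper") gating expensive evaluations.

The surrogate is a fully connected multilayer perceptron mapping the six
normalized parameters to the scalar cost: four ReLU hidden layers of 40
nodes, dropout 0.10 after each hidden layer during training, a per-unit
max-norm constraint of 5.0 on every hidden weight matrix, and a linear
output.  Training uses Adam with mean-squared-error loss and early
stopping on a held-out validation split; the best-validation weights are
restored at the end.

Below a minimum number of observations the trainer refuses and returns a
pass-through surrogate whose gate never skips, so a cold-start loop
degenerates gracefully to plain optimization.

The network is implemented directly on numpy arrays: it is tiny (a few
thousand weights), must be retrained hundreds of times inside the
optimization loop, and has to be bit-reproducible under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "MapperConfig",
    "TrainingSet",
    "SkipDecision",
    "CostSurrogate",
    "PassThroughSurrogate",
    "train_mapper",
    "predict_cost",
    "should_skip",
    "save_surrogate",
    "load_surrogate",
]


@dataclass(frozen=True)
class MapperConfig:
    """Architecture and training hyperparameters of the surrogate."""

    n_hidden_layers: int = 4
    n_nodes: int = 40
    dropout: float = 0.10
    max_norm: float = 5.0
    patience: int = 50
    val_fraction: float = 0.2
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 150
    min_rows: int = 20
    #: fit log(cost + log_floor) instead of the raw cost; costs span orders
    #: of magnitude across the box and the gate needs relative accuracy
    #: near the minimum, which a raw-MSE fit cannot deliver
    log_targets: bool = True
    log_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.n_hidden_layers < 1 or self.n_nodes < 1:
            raise ValueError("need at least one hidden layer with one node")


@dataclass(frozen=True)
class TrainingSet:
    """Rows of (normalized parameter 6-vector, observed cost)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, d) with one target per row")
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
            raise ValueError("inputs must lie in the unit cube")
        if not np.all(np.isfinite(y)):
            raise ValueError("training targets must be finite")
        if np.any(y < 0):
            raise ValueError("costs are non-negative by definition")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class SkipDecision:
    predicted_cost: Optional[float]
    threshold: float
    skipped: bool


class CostSurrogate:
    """A trained MLP predicting cost from normalized parameters."""

    def __init__(self, weights: List[np.ndarray], biases: List[np.ndarray],
                 y_mean: float, y_scale: float, config: MapperConfig):
        self.weights = weights
        self.biases = biases
        self.y_mean = y_mean
        self.y_scale = y_scale
        self.config = config

    trained = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted costs for a batch of unit-cube rows (dropout off)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(f"expected {self.weights[0].shape[0]} features, got {X.shape[1]}")
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
            raise ValueError("surrogate inputs must lie in the unit cube")
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        out = a @ self.weights[-1] + self.biases[-1]
        pred = out.ravel() * self.y_scale + self.y_mean
        if self.config.log_targets:
            pred = np.exp(pred) - self.config.log_floor
        return pred

    def predict_one(self, x: np.ndarray) -> float:
        return float(self.predict(np.atleast_2d(x))[0])


class PassThroughSurrogate:
    """Cold-start stand-in: no predictions, and the gate never skips."""

    trained = False

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - guarded
        raise RuntimeError("pass-through surrogate cannot predict; not enough data to train")

    def predict_one(self, x: np.ndarray) -> float:
        raise RuntimeError("pass-through surrogate cannot predict; not enough data to train")


def _init_layers(sizes: List[int], rng: np.random.Generator
                 ) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        # He initialization, appropriate for ReLU layers
        weights.append(rng.standard_normal((fan_in, fan_out)) * math.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _apply_max_norm(weights: List[np.ndarray], max_norm: float) -> None:
    # constrain the incoming-weight vector of every hidden unit
    for W in weights[:-1]:
        norms = np.linalg.norm(W, axis=0, keepdims=True)
        np.divide(W * max_norm, norms, out=W, where=norms > max_norm)


def train_mapper(data: TrainingSet, config: MapperConfig = MapperConfig()):
    """Train the surrogate on ``data``; returns a pass-through below ``min_rows``.

    Deterministic for a fixed ``config.seed`` and fixed data.
    """
    n = len(data)
    if n < config.min_rows:
        return PassThroughSurrogate()

    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_tr, y_tr = data.X[train_idx], data.y[train_idx]
    X_va, y_va = data.X[val_idx], data.y[val_idx]

    if config.log_targets:
        y_tr = np.log(y_tr + config.log_floor)
        y_va = np.log(y_va + config.log_floor)

    # standardize targets for conditioning; undone at prediction time
    y_mean = float(np.mean(y_tr))
    y_scale = float(np.std(y_tr)) or 1.0
    t_tr = (y_tr - y_mean) / y_scale
    t_va = (y_va - y_mean) / y_scale

    sizes = [data.X.shape[1]] + [config.n_nodes] * config.n_hidden_layers + [1]
    weights, biases = _init_layers(sizes, rng)

    # Adam state
    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0

    def _val_loss() -> float:
        a = X_va
        for W, b in zip(weights[:-1], biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        pred = (a @ weights[-1] + biases[-1]).ravel()
        return float(np.mean((pred - t_va) ** 2))

    best_val = math.inf
    best_snapshot = ([W.copy() for W in weights], [b.copy() for b in biases])
    stale = 0
    keep = 1.0 - config.dropout

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(t_tr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb = X_tr[idx], t_tr[idx]

            # forward with inverted dropout on hidden activations
            activations = [xb]
            masks = []
            a = xb
            for W, b in zip(weights[:-1], biases[:-1]):
                a = np.maximum(a @ W + b, 0.0)
                if config.dropout > 0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                activations.append(a)
            pred = (a @ weights[-1] + biases[-1]).ravel()

            # backward (MSE)
            grad_out = (2.0 / len(tb)) * (pred - tb)[:, None]
            g_w = [None] * len(weights)
            g_b = [None] * len(biases)
            delta = grad_out
            g_w[-1] = activations[-1].T @ delta
            g_b[-1] = delta.sum(axis=0)
            delta = delta @ weights[-1].T
            for layer in range(len(weights) - 2, -1, -1):
                if masks[layer] is not None:
                    delta = delta * masks[layer]
                delta = delta * (activations[layer + 1] > 0)
                g_w[layer] = activations[layer].T @ delta
                g_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T

            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for i in range(len(weights)):
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * g_w[i]
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * g_w[i] ** 2
                weights[i] -= lr * (m_w[i] / corr1) / (np.sqrt(v_w[i] / corr2) + eps_adam)
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * g_b[i]
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * g_b[i] ** 2
                biases[i] -= lr * (m_b[i] / corr1) / (np.sqrt(v_b[i] / corr2) + eps_adam)
            _apply_max_norm(weights, config.max_norm)

        val = _val_loss()
        if val < best_val - 1e-12:
            best_val = val
            best_snapshot = ([W.copy() for W in weights], [b.copy() for b in biases])
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    weights, biases = best_snapshot
    return CostSurrogate(weights, biases, y_mean, y_scale, config)


def predict_cost(surrogate, params_normalized: np.ndarray) -> float:
    """Predicted cost at one unit-cube point (errors on out-of-range input)."""
    x = np.asarray(params_normalized, dtype=float)
    if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
        raise ValueError(f"normalized parameters outside [0, 1]: {x}")
    return surrogate.predict_one(x)


def should_skip(surrogate, params_normalized: np.ndarray, threshold: float) -> SkipDecision:
    """Gate: skip the true evaluation iff the predicted cost exceeds ``threshold``.

    A pass-through (untrained) surrogate never skips.
    """
    if not getattr(surrogate, "trained", False):
        return SkipDecision(predicted_cost=None, threshold=threshold, skipped=False)
    predicted = predict_cost(surrogate, params_normalized)
    return SkipDecision(predicted_cost=predicted, threshold=threshold,
                        skipped=bool(predicted > threshold))


def save_surrogate(surrogate: CostSurrogate, path) -> None:
    """Serialize config + weights to a single JSON artifact."""
    if not getattr(surrogate, "trained", False):
        raise ValueError("cannot serialize an untrained (pass-through) surrogate")
    payload = {
        "config": asdict(surrogate.config),
        "y_mean": surrogate.y_mean,
        "y_scale": surrogate.y_scale,
        "weights": [W.tolist() for W in surrogate.weights],
        "biases": [b.tolist() for b in surrogate.biases],
    }
    Path(path).write_text(json.dumps(payload))


def load_surrogate(path) -> CostSurrogate:
    payload = json.loads(Path(path).read_text())
    return CostSurrogate(
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        y_mean=float(payload["y_mean"]),
        y_scale=float(payload["y_scale"]),
        config=MapperConfig(**payload["config"]),
    )
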