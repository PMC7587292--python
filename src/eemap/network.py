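"""Parametric embedding map: a feedforward network Net_theta : R^D -> R^d and
full-batch training of the elastic-embedding objective through it.

The embedding coordinates are no longer free variables; each cell's coordinate
is the network's output for that cell's expression profile.  Training
backpropagates the closed-form coordinate gradient through the network:

    dE/dtheta = sum_n (dE/dx_n)^T dNet_theta(y_n)/dtheta

so the trained map generalizes: unseen cells are embedded by a forward pass,
without re-optimization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .affinities import AffinityPair
from .containers import Embedding, ExpressionMatrix, FormatError
from .ee import ee_gradient, ee_objective

FORMAT_VERSION = 1

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f') with f' expressed in terms of the activation output
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda a: a * (1.0 - a),
    ),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(np.float64)),
}


@dataclass
class NetworkMapping:
    """Layer dimensions [D, h_1, ..., h_L, d] and parameters theta.

    Hidden layers use the named elementwise nonlinearity; the output layer is
    the identity (an affine read-out of the last hidden representation).
    """

    layer_dims: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 3:
            raise ValueError("network needs at least one hidden layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(_ACTIVATIONS)}"
            )
        n_layers = len(self.layer_dims) - 1
        if len(self.weights) != n_layers or len(self.biases) != n_layers:
            raise ValueError("parameter count inconsistent with layer_dims")
        for k in range(n_layers):
            expect = (self.layer_dims[k], self.layer_dims[k + 1])
            if self.weights[k].shape != expect:
                raise ValueError(f"weight {k} has shape {self.weights[k].shape}, expected {expect}")
            if self.biases[k].shape != (self.layer_dims[k + 1],):
                raise ValueError(f"bias {k} has wrong shape")
            if not (np.all(np.isfinite(self.weights[k])) and np.all(np.isfinite(self.biases[k]))):
                raise ValueError(f"layer {k} has non-finite parameters")

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]

    @property
    def output_dim(self) -> int:
        return self.layer_dims[-1]

    def parameters(self) -> list[np.ndarray]:
        return list(self.weights) + list(self.biases)

    def copy(self) -> "NetworkMapping":
        return NetworkMapping(
            list(self.layer_dims),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
        )


@dataclass
class TrainConfig:
    """First-order training controls.

    The learning rate absorbs any constant scale on the averaged gradient
    (the offset constant of the mini-batch scheme is folded in here).
    Stopping: ``max_epochs`` reached, or the relative objective change over
    the last ``patience`` epochs falls below ``tol``.
    """

    learning_rate: float = 1e-3
    max_epochs: int = 500
    tol: float = 1e-5
    patience: int = 10
    seed: int = 0
    optimizer: str = "adam"
    batch_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


def init_network(
    D: int,
    d: int,
    hidden_dims: Sequence[int] = (500, 100),
    seed: int = 0,
    activation: str = "tanh",
) -> NetworkMapping:
    """Seeded fan-in-scaled initialization.

    Weights of layer k are uniform on [-sqrt(3/fan_in), +sqrt(3/fan_in)],
    giving variance 1/fan_in; biases start at zero.
    """
    if D < 1 or d < 1:
        raise ValueError("D and d must be >= 1")
    if not hidden_dims:
        raise ValueError("hidden_dims must be non-empty")
    dims = [int(D)] + [int(h) for h in hidden_dims] + [int(d)]
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = math.sqrt(3.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkMapping(dims, weights, biases, activation)


def _forward_cached(net: NetworkMapping, y: np.ndarray) -> list[np.ndarray]:
    """Per-layer outputs [a_0=y, a_1, ..., a_L=x]; hidden layers nonlinear,
    output layer affine."""
    act, _ = _ACTIVATIONS[net.activation]
    a = [y]
    h = y
    last = len(net.weights) - 1
    for k, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = h @ w + b
        h = z if k == last else act(z)
        a.append(h)
    return a


def forward_map(net: NetworkMapping, m: ExpressionMatrix | np.ndarray) -> Embedding:
    """Embed cells by a forward pass; rows map independently."""
    y = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=np.float64)
    if y.shape[1] != net.input_dim:
        raise ValueError(
            f"input has {y.shape[1]} features but the network expects {net.input_dim}"
        )
    coords = _forward_cached(net, y)[-1]
    ids = m.cell_ids if isinstance(m, ExpressionMatrix) else None
    return Embedding(coords, ids)


def parameter_gradient(
    net: NetworkMapping, y: np.ndarray, dx: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backpropagate a coordinate-space gradient dE/dX (N x d) to theta.

    Returns (weight gradients, bias gradients), each aligned with the
    network's parameter lists.
    """
    _, dact = _ACTIVATIONS[net.activation]
    a = _forward_cached(net, y)
    gw = [np.empty(0)] * len(net.weights)
    gb = [np.empty(0)] * len(net.biases)
    delta = dx  # output layer is identity, so dE/dz_L = dE/dx
    for k in range(len(net.weights) - 1, -1, -1):
        gw[k] = a[k].T @ delta
        gb[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ net.weights[k].T) * dact(a[k])
    return gw, gb


def ee_parameter_gradient(
    net: NetworkMapping, y: np.ndarray, a: AffinityPair
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Objective value and full parameter gradient of E(Net_theta(Y)).

    This single code path serves both the full-batch trainer and (per batch)
    the stochastic trainer.
    """
    x = _forward_cached(net, y)[-1]
    dx = ee_gradient(x, a)
    gw, gb = parameter_gradient(net, y, dx)
    return gw, gb, ee_objective(x, a)


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Adam:
    """Adaptive-moment first-order optimizer (bias-corrected)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params: list[np.ndarray], lr: float):
    if name == "adam":
        return Adam(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}; use 'adam' or 'sgd'")


def _should_stop(trace: list[float], tol: float, patience: int) -> bool:
    if len(trace) <= patience:
        return False
    prev, cur = trace[-patience - 1], trace[-1]
    return abs(prev - cur) < tol * max(1.0, abs(prev))


def train_full_batch(
    m: ExpressionMatrix,
    a: AffinityPair,
    net: NetworkMapping,
    cfg: TrainConfig,
) -> tuple[NetworkMapping, Embedding, np.ndarray]:
    """Train Net_theta on the full dataset; returns (net, embedding, trace).

    Each epoch evaluates the objective and its full parameter gradient and
    applies one optimizer step.  The trace records the per-epoch objective
    values (evaluated before each step).  The network is updated in place and
    also returned.
    """
    if m.n_cells != a.n:
        raise ValueError("affinities were not computed on this matrix")
    if m.n_genes != net.input_dim:
        raise ValueError(
            f"matrix has {m.n_genes} features but the network expects {net.input_dim}"
        )
    opt = make_optimizer(cfg.optimizer, net.parameters(), cfg.learning_rate)
    trace: list[float] = []
    for epoch in range(cfg.max_epochs):
        gw, gb, obj = ee_parameter_gradient(net, m.values, a)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at epoch {epoch}")
        trace.append(obj)
        opt.step(gw + gb)
        if _should_stop(trace, cfg.tol, cfg.patience):
            break
    emb = forward_map(net, m)
    return net, emb, np.asarray(trace)


# ---------------------------------------------------------------------------
# persistence: versioned JSON container, bit-exact round-trip


def save_mapping(net: NetworkMapping, path: str | Path) -> None:
    """Write the mapping as a versioned JSON container.

    Floats are serialized with Python's shortest round-trip repr, so a
    save/load cycle is bit-exact.
    """
    doc = {
        "format_version": FORMAT_VERSION,
        "layer_dims": net.layer_dims,
        "activation": net.activation,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
    }
    Path(path).write_text(json.dumps(doc))


def load_mapping(path: str | Path) -> NetworkMapping:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"not a valid mapping file: {e}") from e
    for key in ("format_version", "layer_dims", "activation", "weights", "biases"):
        if key not in doc:
            raise FormatError(f"mapping file is missing field {key!r}")
    if doc["format_version"] != FORMAT_VERSION:
        raise FormatError(f"unsupported format_version {doc['format_version']}")
    return NetworkMapping(
        [int(x) for x in doc["layer_dims"]],
        [np.asarray(w, dtype=np.float64) for w in doc["weights"]],
        [np.asarray(b, dtype=np.float64) for b in doc["biases"]],
        doc["activation"],
    )
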