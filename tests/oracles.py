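"""Independent brute-force oracles used only by the test suite.

Naive double-loop / elementwise implementations with no shared arithmetic
with the production modules, so agreement between the two is evidence of
correctness rather than tautology.  Size guards keep them honest: they refuse
anything beyond tiny instances.
"""

from __future__ import annotations

import math

import numpy as np

_MAX_N = 50
_MAX_PARAMS = 1000


def _guard_n(n: int) -> None:
    if n > _MAX_N:
        raise ValueError(f"oracle limited to N <= {_MAX_N}, got {n}")


def brute_objective(coords: np.ndarray, wplus, wminus, lam: float) -> float:
    """Elastic-embedding objective by explicit double loop over ordered pairs."""
    n = coords.shape[0]
    _guard_n(n)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = sum((coords[i, t] - coords[j, t]) ** 2 for t in range(coords.shape[1]))
            total += wplus[i][j] * d2 + lam * wminus[i][j] * math.exp(-d2)
    return total


def brute_coordinate_gradient(coords: np.ndarray, wplus, wminus, lam: float) -> np.ndarray:
    """dE/dx_n by the closed form, evaluated scalar-by-scalar."""
    n, d = coords.shape
    _guard_n(n)
    g = np.zeros((n, d))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = sum((coords[i, t] - coords[j, t]) ** 2 for t in range(d))
            coef = 4.0 * (wplus[i][j] - lam * wminus[i][j] * math.exp(-d2))
            for t in range(d):
                g[i, t] += coef * (coords[i, t] - coords[j, t])
    return g


def fd_coordinate_gradient(objective, coords: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar objective over coordinates."""
    _guard_n(coords.shape[0])
    g = np.zeros_like(coords)
    for idx in np.ndindex(*coords.shape):
        plus = coords.copy()
        minus = coords.copy()
        plus[idx] += step
        minus[idx] -= step
        g[idx] = (objective(plus) - objective(minus)) / (2 * step)
    return g


def fd_parameter_gradient(net, y: np.ndarray, objective_of_params, step: float = 1e-5):
    """Central finite differences of E(Net_theta(Y)) over every theta entry.

    ``objective_of_params(net)`` must evaluate the scalar objective for the
    network's current parameters.  Returns (weight grads, bias grads).
    """
    n_params = sum(w.size for w in net.weights) + sum(b.size for b in net.biases)
    if n_params > _MAX_PARAMS:
        raise ValueError(f"oracle limited to {_MAX_PARAMS} parameters, got {n_params}")
    _guard_n(y.shape[0])

    def fd_array(arr):
        g = np.zeros_like(arr)
        for idx in np.ndindex(*arr.shape):
            orig = arr[idx]
            arr[idx] = orig + step
            f_plus = objective_of_params(net)
            arr[idx] = orig - step
            f_minus = objective_of_params(net)
            arr[idx] = orig
            g[idx] = (f_plus - f_minus) / (2 * step)
        return g

    return [fd_array(w) for w in net.weights], [fd_array(b) for b in net.biases]


def brute_knn(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    """Exhaustive KNN: sort all distances per query (ties by lower train
    index), majority vote (ties by smallest label)."""
    _guard_n(x_train.shape[0])
    preds = np.zeros(x_test.shape[0], dtype=int)
    for q in range(x_test.shape[0]):
        dists = [
            (sum((x_test[q, t] - x_train[i, t]) ** 2 for t in range(x_train.shape[1])), i)
            for i in range(x_train.shape[0])
        ]
        dists.sort()  # lexicographic: distance, then train index
        votes = [y_train[i] for _, i in dists[:k]]
        best_label, best_count = None, -1
        for label in sorted(set(votes)):
            c = votes.count(label)
            if c > best_count:
                best_label, best_count = label, c
        preds[q] = best_label
    return preds
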