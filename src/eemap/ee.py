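"""The elastic-embedding objective, its closed-form coordinate gradient, and a
non-parametric optimizer over free embedding coordinates.

The objective over an embedding X = (x_1 .. x_N) is

    E(X) = sum_{n != m} w+_nm ||x_n - x_m||^2
         + lam * sum_{n != m} w-_nm exp(-||x_n - x_m||^2)

with both sums over ordered pairs, exactly as written.  The attractive term
pulls similar cells together; the repulsive term pushes dissimilar cells apart
with a Gaussian decay, so it only acts at short range and the embedding
reaches a finite equilibrium spread.

The gradient with respect to x_n has the closed form

    dE/dx_n = 4 * sum_{m != n} (w+_nm - lam * w-_nm * exp(-||x_n - x_m||^2))
                               * (x_n - x_m)

which is what both the free-coordinate optimizer here and the parametric
network trainer backpropagate.
"""

from __future__ import annotations

import numpy as np

from .affinities import AffinityPair, squared_distances
from .containers import Embedding


def _coords(x: Embedding | np.ndarray) -> np.ndarray:
    return x.coords if isinstance(x, Embedding) else np.asarray(x, dtype=np.float64)


def _check_dims(coords: np.ndarray, a: AffinityPair) -> None:
    if coords.shape[0] != a.n:
        raise ValueError(
            f"embedding has {coords.shape[0]} rows but affinities are {a.n} x {a.n}"
        )


def ee_objective(x: Embedding | np.ndarray, a: AffinityPair) -> float:
    """Evaluate E(X); ordered-pair sums, so symmetric weights count twice."""
    coords = _coords(x)
    _check_dims(coords, a)
    d2 = squared_distances(coords)
    attract = float(np.sum(a.wplus * d2))
    # wminus has zero diagonal, so the exp(0)=1 self-terms contribute nothing
    repel = float(np.sum(a.wminus * np.exp(-d2)))
    return attract + a.lam * repel


def ee_gradient(x: Embedding | np.ndarray, a: AffinityPair) -> np.ndarray:
    """Closed-form N x d gradient of :func:`ee_objective`."""
    coords = _coords(x)
    _check_dims(coords, a)
    d2 = squared_distances(coords)
    m = a.wplus - a.lam * a.wminus * np.exp(-d2)
    np.fill_diagonal(m, 0.0)
    return 4.0 * (m.sum(axis=1)[:, None] * coords - m @ coords)


def optimize_free_embedding(
    a: AffinityPair,
    d: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    init: str = "gaussian",
    init_scale: float = 1e-2,
    initial_step: float = 1.0,
    return_trace: bool = False,
):
    """Minimize E(X) directly over free coordinates by steepest descent with
    Armijo backtracking (factor 0.5, c = 1e-4).

    This is the non-parametric elastic-embedding baseline: every accepted step
    decreases the objective, so the recorded trace is non-increasing.
    Initialization is a seeded Gaussian of scale ``init_scale`` (default), or
    the first ``d`` principal directions of the W+ rows (``init='pca'``).

    Returns an :class:`Embedding`, or ``(Embedding, trace)`` when
    ``return_trace`` is set.
    """
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    rng = np.random.default_rng(seed)
    if init == "gaussian":
        coords = init_scale * rng.standard_normal((a.n, d))
    elif init == "pca":
        centered = a.wplus - a.wplus.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        coords = init_scale * u[:, :d] * s[:d]
    else:
        raise ValueError(f"unknown init {init!r}; use 'gaussian' or 'pca'")

    c_armijo = 1e-4
    step = initial_step
    f = ee_objective(coords, a)
    trace = [f]
    for it in range(max_iter):
        g = ee_gradient(coords, a)
        gnorm2 = float(np.sum(g * g))
        if gnorm2 == 0.0:
            break
        accepted = False
        t = step
        for _ in range(60):
            cand = coords - t * g
            f_new = ee_objective(cand, a)
            if not np.isfinite(f_new):
                t *= 0.5
                continue
            if f_new <= f - c_armijo * t * gnorm2:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # no decrease possible at machine precision
        coords, f_prev, f = cand, f, f_new
        trace.append(f)
        step = 2.0 * t  # warm-start the next line search
        if not np.isfinite(f):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        if abs(f_prev - f) < tol * max(1.0, abs(f_prev)):
            break
    emb = Embedding(coords)
    return (emb, np.asarray(trace)) if return_trace else emb
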