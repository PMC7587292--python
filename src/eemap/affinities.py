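"""Attractive (W+) and repulsive (W-) weight matrices of the elastic-embedding
objective.

W+ encodes similarity in the high-dimensional space, either as fixed-bandwidth
Gaussian affinities or as entropic affinities, where each point's bandwidth is
tuned by bisection so its conditional neighbor distribution has a prescribed
perplexity.  W- encodes dissimilarity and defaults to squared Euclidean
distance (a ``plain`` distance dialect is also provided).  Both matrices are
exactly symmetric with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix

#: bisection controls for entropic affinities
_BETA_LO = 1e-20
_BETA_HI = 1e20
_MAX_ITER = 200
_ENTROPY_TOL = 1e-5


class ConvergenceError(RuntimeError):
    pass


@dataclass
class AffinityPair:
    """Symmetric attractive and repulsive weights plus the trade-off lam.

    The elastic-embedding objective is
    ``E(X) = sum_{n != m} wplus_nm ||x_n - x_m||^2
           + lam * sum_{n != m} wminus_nm exp(-||x_n - x_m||^2)``.
    """

    wplus: np.ndarray
    wminus: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.wplus = np.asarray(self.wplus, dtype=np.float64)
        self.wminus = np.asarray(self.wminus, dtype=np.float64)
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        for name, w in (("wplus", self.wplus), ("wminus", self.wminus)):
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(w < 0):
                raise ValueError(f"{name} contains negative entries")
            if not np.array_equal(w, w.T):
                raise ValueError(f"{name} is not exactly symmetric")
            if np.any(np.diagonal(w) != 0):
                raise ValueError(f"{name} diagonal is not zero")
        if self.wplus.shape != self.wminus.shape:
            raise ValueError("wplus and wminus shapes differ")

    @property
    def n(self) -> int:
        return self.wplus.shape[0]


def squared_distances(m: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between cells (rows).

    Exactly symmetric, zero diagonal, clamped at 0 against round-off.
    """
    y = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=np.float64)
    sq = np.einsum("ij,ij->i", y, y)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
    d2 = 0.5 * (d2 + d2.T)  # enforce exact symmetry
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def gaussian_affinities(m: ExpressionMatrix | np.ndarray, sigma: float) -> np.ndarray:
    """W+ with a single global bandwidth: w_nm = exp(-d_nm^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    w = np.exp(-squared_distances(m) / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w


def conditional_gaussian(
    d2: np.ndarray, perplexity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized conditional distributions p_{m|n} with per-point
    bandwidths beta_n found by bisection so each row's Shannon entropy
    (natural log) equals ln(perplexity).

    Returns ``(P, beta)`` where P has zero diagonal and rows summing to 1.
    """
    n = d2.shape[0]
    if not 1.0 < perplexity <= n - 1:
        raise ValueError(f"perplexity must be in (1, {n - 1}], got {perplexity}")
    target = np.log(perplexity)
    # shift each row by its off-diagonal minimum for numerical stability;
    # entropy is invariant to the shift
    off = d2 + np.diag(np.full(n, np.inf))
    shift = off.min(axis=1)
    s = np.maximum(d2 - shift[:, None], 0.0)

    lo = np.full(n, _BETA_LO)
    hi = np.full(n, _BETA_HI)
    beta = np.sqrt(lo * hi)  # geometric midpoint suits the huge bracket
    mask = ~np.eye(n, dtype=bool)
    h = np.empty(n)
    p = np.empty_like(d2)
    for _ in range(_MAX_ITER):
        np.exp(-beta[:, None] * s, where=mask, out=p)
        p[~mask] = 0.0
        z = p.sum(axis=1)
        mean_s = (p * s).sum(axis=1) / z
        h = np.log(z) + beta * mean_s
        done = np.abs(h - target) < _ENTROPY_TOL
        if done.all():
            break
        # entropy decreases with beta
        too_high = h > target
        lo = np.where(too_high & ~done, beta, lo)
        hi = np.where(~too_high & ~done, beta, hi)
        mid_geo = np.sqrt(lo * hi)
        mid_ari = 0.5 * (lo + hi)
        # geometric steps while the bracket spans orders of magnitude,
        # arithmetic once it has narrowed
        beta = np.where(done, beta, np.where(hi / lo > 10.0, mid_geo, mid_ari))
    else:
        bad = np.argwhere(np.abs(h - target) >= _ENTROPY_TOL).ravel()
        raise ConvergenceError(
            f"entropic bisection failed to converge for point(s) {bad.tolist()} "
            f"after {_MAX_ITER} iterations"
        )
    p /= p.sum(axis=1, keepdims=True)
    return p, beta


def entropic_affinities(
    m: ExpressionMatrix | np.ndarray, perplexity: float
) -> np.ndarray:
    """W+ from entropic affinities: symmetrized (P + P^T)/2, zero diagonal."""
    d2 = squared_distances(m)
    p, _ = conditional_gaussian(d2, perplexity)
    w = 0.5 * (p + p.T)
    np.fill_diagonal(w, 0.0)
    return w


def repulsive_weights(
    m: ExpressionMatrix | np.ndarray, dialect: str = "squared"
) -> np.ndarray:
    """W- from Euclidean distances: ``squared`` (default) -> d^2, ``plain`` -> d."""
    d2 = squared_distances(m)
    if dialect == "squared":
        return d2
    if dialect == "plain":
        return np.sqrt(d2)
    raise ValueError(f"unknown repulsive dialect {dialect!r}; use 'squared' or 'plain'")


def build_affinity_pair(
    m: ExpressionMatrix | np.ndarray,
    mode: str = "entropic",
    parameter: float = 30.0,
    lam: float = 1.0,
    repulsive_dialect: str = "squared",
    normalize: str = "unit",
) -> AffinityPair:
    """Assemble W+ (per ``mode``: 'gaussian' sigma or 'entropic' perplexity),
    W- and lam into a validated :class:`AffinityPair`.

    ``normalize='unit'`` (default) scales each matrix to total sum 1 so that
    lam directly trades off the attractive and repulsive terms; without it the
    repulsive weights (raw distances) dwarf the attractive affinities by
    orders of magnitude and lam loses its meaning.  ``normalize='none'``
    keeps the raw matrices.
    """
    if mode == "gaussian":
        wplus = gaussian_affinities(m, parameter)
    elif mode == "entropic":
        wplus = entropic_affinities(m, parameter)
    else:
        raise ValueError(f"unknown affinity mode {mode!r}; use 'gaussian' or 'entropic'")
    wminus = repulsive_weights(m, repulsive_dialect)
    if normalize == "unit":
        # guard: an all-duplicate batch has wminus identically zero
        if wplus.sum() > 0:
            wplus = wplus / wplus.sum()
        if wminus.sum() > 0:
            wminus = wminus / wminus.sum()
    elif normalize != "none":
        raise ValueError(f"unknown normalize {normalize!r}; use 'unit' or 'none'")
    return AffinityPair(wplus, wminus, lam)


def save_affinities(a: AffinityPair, directory: str | Path) -> None:
    """Persist an affinity pair as MatrixMarket files (offline batch caching)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "wplus.mtx"), scipy.sparse.coo_matrix(a.wplus))
    scipy.io.mmwrite(str(directory / "wminus.mtx"), scipy.sparse.coo_matrix(a.wminus))
    (directory / "lam.txt").write_text(repr(a.lam) + "\n")


def load_affinities(directory: str | Path) -> AffinityPair:
    directory = Path(directory)
    wplus = np.asarray(scipy.io.mmread(directory / "wplus.mtx").todense())
    wminus = np.asarray(scipy.io.mmread(directory / "wminus.mtx").todense())
    lam = float((directory / "lam.txt").read_text())
    return AffinityPair(wplus, wminus, lam)
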