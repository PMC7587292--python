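"""Embedding quality via K-nearest-neighbor cross-validation, and the
subsample-train / map-all generalizability experiment.

The generalization error of an embedding is the minimum, over K in [1, 40],
of the 10-fold cross-validated KNN misclassification rate computed in the
embedded space against known cell labels.  Folds are stratified and fixed
across K so every K is compared on the same splits.  Determinism: equidistant
neighbors are broken by lower training index, vote ties by smallest class
label.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .affinities import build_affinity_pair
from .containers import Embedding, ExpressionMatrix
from .network import TrainConfig, forward_map, init_network, train_full_batch


@dataclass
class EvalResult:
    """KNN-CV error for each K and its minimum (the generalization error)."""

    errors_by_k: dict[int, float]
    k_range: tuple[int, int]

    def __post_init__(self) -> None:
        for k, e in self.errors_by_k.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"error rate for K={k} outside [0,1]: {e}")

    @property
    def generalization_error(self) -> float:
        return min(self.errors_by_k.values())


def _encode_labels(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    return classes, y


def _knn_predict_multi(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
    ks: Sequence[int], n_classes: int,
) -> dict[int, np.ndarray]:
    """Majority-vote KNN predictions for several K from one neighbor sort.

    Stable argsort breaks distance ties by lower training index; bincount
    argmax breaks vote ties by smallest class label.
    """
    d = cdist(test_x, train_x, metric="sqeuclidean")
    order = np.argsort(d, axis=1, kind="stable")
    out = {}
    for k in ks:
        votes = train_y[order[:, :k]]
        counts = np.apply_along_axis(np.bincount, 1, votes, minlength=n_classes)
        out[k] = counts.argmax(axis=1)
    return out


def _cv_errors(
    coords: np.ndarray, y: np.ndarray, ks: Sequence[int], n_folds: int, seed: int
) -> dict[int, float]:
    n_classes = int(y.max()) + 1
    class_counts = np.bincount(y)
    small = np.argwhere(class_counts < n_folds).ravel()
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than n_folds={n_folds} members; "
            "stratified folding is impossible"
        )
    max_k = max(ks)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_errors = {k: [] for k in ks}
    for train_idx, test_idx in skf.split(coords, y):
        if max_k > len(train_idx):
            raise ValueError(f"K={max_k} exceeds training-fold size {len(train_idx)}")
        preds = _knn_predict_multi(
            coords[train_idx], y[train_idx], coords[test_idx], ks, n_classes
        )
        for k, pred in preds.items():
            fold_errors[k].append(float(np.mean(pred != y[test_idx])))
    return {k: float(np.mean(v)) for k, v in fold_errors.items()}


def knn_cv_error(
    x: Embedding | np.ndarray,
    labels: Sequence,
    k: int = 1,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean 10-fold (by default) CV misclassification rate of a K-NN
    classifier in the embedded space."""
    coords = x.coords if isinstance(x, Embedding) else np.asarray(x, dtype=np.float64)
    if len(labels) != coords.shape[0]:
        raise ValueError("labels length does not match embedding rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    _, y = _encode_labels(labels)
    return _cv_errors(coords, y, [k], n_folds, seed)[k]


def generalization_error(
    x: Embedding | np.ndarray,
    labels: Sequence,
    k_max: int = 40,
    n_folds: int = 10,
    seed: int = 0,
) -> EvalResult:
    """CV error for every K in [1, k_max] on one shared fold assignment,
    plus the minimum over K."""
    coords = x.coords if isinstance(x, Embedding) else np.asarray(x, dtype=np.float64)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    _, y = _encode_labels(labels)
    ks = list(range(1, k_max + 1))
    return EvalResult(_cv_errors(coords, y, ks, n_folds, seed), (1, k_max))


@dataclass
class SubsampleResult:
    """Output of the subsample-train / map-all experiment."""

    indices: np.ndarray
    train_embedding: Embedding
    mapped_embedding: Embedding
    train_eval: EvalResult
    mapped_eval: EvalResult


def subsample_generalization_experiment(
    m: ExpressionMatrix,
    labels: Sequence,
    scale: float,
    mode: str = "entropic",
    parameter: float = 30.0,
    lam: float = 1.0,
    hidden_dims: Sequence[int] = (500, 100),
    d: int = 2,
    cfg: Optional[TrainConfig] = None,
    k_max: int = 40,
    n_folds: int = 10,
) -> SubsampleResult:
    """Train on a seeded uniform subsample, then map every cell out-of-sample.

    At ``scale=1.0`` the subsample is the full dataset and the two embeddings
    coincide row for row.  Evaluation runs on both the subsample embedding
    (subsample labels) and the mapped-all embedding (all labels).
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    cfg = cfg or TrainConfig()
    n_sub = floor(scale * m.n_cells)
    if n_sub < 2:
        raise ValueError("subsample would have fewer than 2 cells")
    rng = np.random.default_rng(cfg.seed)
    idx = np.sort(rng.choice(m.n_cells, size=n_sub, replace=False))
    sub = m.subset_cells(idx)
    labels = np.asarray(labels)
    aff = build_affinity_pair(sub, mode=mode, parameter=parameter, lam=lam)
    net = init_network(m.n_genes, d, hidden_dims, seed=cfg.seed)
    net, train_emb, _ = train_full_batch(sub, aff, net, cfg)
    mapped = forward_map(net, m)
    train_eval = generalization_error(
        train_emb, labels[idx], k_max=k_max, n_folds=n_folds, seed=cfg.seed
    )
    mapped_eval = generalization_error(
        mapped, labels, k_max=k_max, n_folds=n_folds, seed=cfg.seed
    )
    return SubsampleResult(idx, train_emb, mapped, train_eval, mapped_eval)
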