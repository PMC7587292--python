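"""Mini-batch stochastic training of the parametric elastic embedding.

Large datasets make the N x N weight matrices and the coordinate gradient
expensive.  The stochastic variant partitions the cells once into random
batches, precomputes each batch's attractive/repulsive weights offline, and at
every iteration averages the per-batch parameter gradients:

    dE/dtheta ~= (1/|B|) * sum_i sum_{n in b_i} (dE(X_i)/dx_n)^T dNet(y_n)/dtheta

with the coordinate gradient evaluated within each batch.  Any constant scale
on this average is absorbed by the learning rate.  With a single batch the
scheme reduces exactly — bitwise, at identical parameters — to full-batch
training.

Newly observed data can be folded in by forming it into new batches and
continuing optimization from the current parameters (online updating).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .affinities import AffinityPair, build_affinity_pair
from .containers import Embedding, ExpressionMatrix
from .network import (
    NetworkMapping,
    TrainConfig,
    _should_stop,
    ee_parameter_gradient,
    forward_map,
    make_optimizer,
)


@dataclass
class BatchPartition:
    """Random disjoint index sets covering {0..N-1}, with optional per-batch
    affinities computed offline.

    Indices within each batch are kept sorted (batches are sets; a canonical
    order makes single-batch training coincide bitwise with full-batch).
    """

    batches: list[np.ndarray]
    n_total: int
    seed: int = 0
    per_batch_affinities: Optional[list[AffinityPair]] = None
    affinity_params: Optional[dict] = None

    def __post_init__(self) -> None:
        allidx = np.concatenate(self.batches) if self.batches else np.empty(0, int)
        if len(allidx) != self.n_total or len(np.unique(allidx)) != self.n_total:
            raise ValueError("batches must be disjoint and cover all indices")
        if any(len(b) < 2 for b in self.batches):
            raise ValueError("every batch needs at least 2 cells")
        if self.per_batch_affinities is not None:
            if len(self.per_batch_affinities) != len(self.batches):
                raise ValueError("per_batch_affinities misaligned with batches")
            for b, a in zip(self.batches, self.per_batch_affinities):
                if a.n != len(b):
                    raise ValueError("per-batch affinity dimension mismatch")

    @property
    def n_batches(self) -> int:
        return len(self.batches)


def partition_batches(N: int, batch_size: int, seed: int = 0) -> BatchPartition:
    """Seeded random partition into ceil(N / batch_size) batches whose sizes
    differ by at most one."""
    if batch_size < 2:
        raise ValueError(f"batch_size must be >= 2, got {batch_size}")
    if batch_size > N:
        raise ValueError(f"batch_size {batch_size} exceeds N={N}")
    n_batches = math.ceil(N / batch_size)
    # a balanced split must not create a batch of fewer than 2 cells
    # (possible only for batch_size 2 and odd N)
    while n_batches > 1 and N // n_batches < 2:
        n_batches -= 1
    perm = np.random.default_rng(seed).permutation(N)
    batches = [np.sort(chunk) for chunk in np.array_split(perm, n_batches)]
    return BatchPartition(batches, n_total=N, seed=seed)


def batch_affinities(
    m: ExpressionMatrix,
    p: BatchPartition,
    mode: str = "entropic",
    parameter: float = 30.0,
    lam: float = 1.0,
    repulsive_dialect: str = "squared",
    normalize: str = "unit",
) -> BatchPartition:
    """Compute each batch's AffinityPair on its submatrix, once, up front."""
    if p.n_total != m.n_cells:
        raise ValueError("partition was not built on this matrix")
    pairs = [
        build_affinity_pair(m.values[b], mode, parameter, lam,
                            repulsive_dialect, normalize)
        for b in p.batches
    ]
    return BatchPartition(
        p.batches,
        p.n_total,
        p.seed,
        per_batch_affinities=pairs,
        affinity_params=dict(
            mode=mode, parameter=parameter, lam=lam,
            repulsive_dialect=repulsive_dialect, normalize=normalize,
        ),
    )


def averaged_gradient(
    m: ExpressionMatrix, p: BatchPartition, net: NetworkMapping
) -> tuple[list[np.ndarray], float]:
    """Batch-averaged parameter gradient and the summed per-batch objective."""
    if p.per_batch_affinities is None:
        raise ValueError("call batch_affinities first (weights are computed offline)")
    total: Optional[list[np.ndarray]] = None
    obj = 0.0
    for b, aff in zip(p.batches, p.per_batch_affinities):
        gw, gb, e = ee_parameter_gradient(net, m.values[b], aff)
        grads = gw + gb
        obj += e
        if total is None:
            total = grads
        else:
            for t, g in zip(total, grads):
                t += g
    assert total is not None
    inv = 1.0 / p.n_batches
    return [t * inv for t in total], obj


def train_stochastic(
    m: ExpressionMatrix,
    p: BatchPartition,
    net: NetworkMapping,
    cfg: TrainConfig,
    cycle_batches: bool = False,
    repartition: bool = False,
) -> tuple[NetworkMapping, Embedding, np.ndarray]:
    """Mini-batch training; returns (net, full-data embedding, trace).

    Default: every iteration averages the gradients of all batches (the
    written scheme).  ``cycle_batches`` instead steps on one batch per
    iteration, round-robin.  ``repartition`` redraws the partition (and
    recomputes the per-batch weights) every epoch; off by default since the
    weights are meant to be computed once, offline.
    """
    if p.per_batch_affinities is None:
        raise ValueError("call batch_affinities first (weights are computed offline)")
    if m.n_genes != net.input_dim:
        raise ValueError(
            f"matrix has {m.n_genes} features but the network expects {net.input_dim}"
        )
    opt = make_optimizer(cfg.optimizer, net.parameters(), cfg.learning_rate)
    trace: list[float] = []
    batch_sizes = [len(b) for b in p.batches]
    for epoch in range(cfg.max_epochs):
        if repartition and epoch > 0:
            ap = p.affinity_params or {}
            newp = partition_batches(p.n_total, max(batch_sizes), seed=p.seed + epoch)
            p = batch_affinities(m, newp, **ap)
        if cycle_batches:
            obj = 0.0
            for b, aff in zip(p.batches, p.per_batch_affinities):
                gw, gb, e = ee_parameter_gradient(net, m.values[b], aff)
                obj += e
                opt.step(gw + gb)
        else:
            grads, obj = averaged_gradient(m, p, net)
            opt.step(grads)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at iteration {epoch}")
        trace.append(obj)
        if _should_stop(trace, cfg.tol, cfg.patience):
            break
    emb = forward_map(net, m)
    return net, emb, np.asarray(trace)


def update_online(
    net: NetworkMapping,
    new_data: ExpressionMatrix,
    cfg: TrainConfig,
    epochs: Optional[int] = None,
    mode: str = "entropic",
    parameter: float = 30.0,
    lam: float = 1.0,
) -> NetworkMapping:
    """Continue training from the current parameters on newly observed cells.

    The new cells are formed into new batches (``cfg.batch_size`` or a single
    batch), their weights computed offline, and ``epochs`` additional
    iterations run (default ``cfg.max_epochs``; 0 leaves theta untouched).
    """
    if new_data.n_genes != net.input_dim:
        raise ValueError(
            f"new data has {new_data.n_genes} features but the network expects "
            f"{net.input_dim}"
        )
    epochs = cfg.max_epochs if epochs is None else epochs
    if epochs == 0:
        return net
    bs = cfg.batch_size or new_data.n_cells
    p = partition_batches(new_data.n_cells, min(bs, new_data.n_cells), seed=cfg.seed)
    p = batch_affinities(new_data, p, mode=mode, parameter=parameter, lam=lam)
    sub_cfg = TrainConfig(
        learning_rate=cfg.learning_rate,
        max_epochs=epochs,
        tol=cfg.tol,
        patience=cfg.patience,
        seed=cfg.seed,
        optimizer=cfg.optimizer,
        batch_size=cfg.batch_size,
    )
    net, _, _ = train_stochastic(new_data, p, net, sub_cfg)
    return net
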