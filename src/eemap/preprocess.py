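"""Feature filtering and normalization applied before affinity computation.

The canonical chain, in order: ``log1p_transform`` -> ``select_top_variance_genes``
-> ``standardize_genes`` -> (optionally, for very high-dimensional data)
``pca_reduce``.  The order matters — variances are compared on the log scale,
and standardization assumes zero-variance genes were already filtered out —
so :func:`run_pipeline` applies exactly this order.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .containers import ExpressionMatrix


def log1p_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each entry v by log(1 + v). Requires non-negative input."""
    if np.any(m.values < 0):
        i, j = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"log1p requires non-negative expression; cell {m.cell_ids[i]!r}, "
            f"gene {m.gene_ids[j]!r} has value {m.values[i, j]}"
        )
    return ExpressionMatrix(np.log1p(m.values), m.cell_ids, m.gene_ids, m.labels)


def gene_variances(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene sample variance (unbiased, n-1 denominator)."""
    return np.var(m.values, axis=0, ddof=1)


def select_top_variance_genes(m: ExpressionMatrix, n_genes: int) -> ExpressionMatrix:
    """Keep the ``n_genes`` highest-variance genes, in their original order.

    Ties are broken by original column index (stable), so the result is
    deterministic across platforms.
    """
    if not 1 <= n_genes <= m.n_genes:
        raise ValueError(f"n_genes must be in [1, {m.n_genes}], got {n_genes}")
    var = gene_variances(m)
    # stable sort on -variance keeps earlier columns first among ties
    top = np.sort(np.argsort(-var, kind="stable")[:n_genes])
    return ExpressionMatrix(
        m.values[:, top], m.cell_ids, [m.gene_ids[j] for j in top], m.labels
    )


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to sample standard deviation 1."""
    sd = np.std(m.values, axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"gene {m.gene_ids[j]!r} has zero variance; run variance filtering "
            "(select_top_variance_genes) before standardizing"
        )
    z = (m.values - np.mean(m.values, axis=0)) / sd
    return ExpressionMatrix(z, m.cell_ids, m.gene_ids, m.labels)


def pca_reduce(m: ExpressionMatrix, n_components: int) -> ExpressionMatrix:
    """Project onto the top principal components of the centered data.

    Components are ordered by decreasing explained variance.  The sign of each
    component is fixed so that its largest-magnitude loading is positive,
    making the scores deterministic.
    """
    max_k = min(m.n_cells, m.n_genes)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
    centered = m.values - m.values.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    return ExpressionMatrix(
        scores, m.cell_ids, [f"PC{i + 1}" for i in range(n_components)], m.labels
    )


def run_pipeline(
    m: ExpressionMatrix,
    log1p: bool = True,
    n_top_genes: Optional[int] = 500,
    standardize: bool = True,
    n_pcs: Optional[int] = None,
) -> ExpressionMatrix:
    """Apply the preprocessing chain in its fixed order.

    log1p -> top-variance gene selection -> per-gene standardization -> PCA.
    Any stage can be switched off; the relative order of enabled stages never
    changes.
    """
    if log1p:
        m = log1p_transform(m)
    if n_top_genes is not None and n_top_genes < m.n_genes:
        m = select_top_variance_genes(m, n_top_genes)
    if standardize:
        m = standardize_genes(m)
    if n_pcs is not None:
        m = pca_reduce(m, n_pcs)
    return m
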