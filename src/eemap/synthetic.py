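"""Synthetic benchmarks: a branching expression tree and Gaussian clusters.

The tree emulates a simulated single-cell trajectory: 10 branches of 144
cells each (1,440 cells total) over 60 genes, where every branch exclusively
expresses its own block of 6 genes, ramping linearly from 0 to a fixed
maximum along the branch.  A branch attached to its parent inherits the
parent's expression state at the attachment point, so the tree is continuous:
a cell expresses its own block (partially) plus the terminal states of all
its ancestors' blocks, and is zero elsewhere before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ExpressionMatrix

#: default topology: root with 3 children, each child with 2 children
#: (10 branches); entries are (parent_branch, attachment_position in [0,1])
DEFAULT_TOPOLOGY: list[tuple[int, float]] = [
    (-1, 0.0),          # 0: root
    (0, 1.0), (0, 1.0), (0, 1.0),      # 1..3 attach to the root's end
    (1, 1.0), (1, 1.0),                # 4,5
    (2, 1.0), (2, 1.0),                # 6,7
    (3, 1.0), (3, 1.0),                # 8,9
]


@dataclass
class TreeSpec:
    """Parameters of the branching-tree generator.

    ``n_branches * cells_per_branch`` cells over ``n_genes`` genes;
    each branch owns ``genes_per_branch`` exclusive genes.  ``noise_sd`` is
    the additive Gaussian noise on a 0-to-``max_expression`` ramp.
    """

    n_branches: int = 10
    cells_per_branch: int = 144
    n_genes: int = 60
    genes_per_branch: int = 6
    noise_sd: float = 0.1
    max_expression: float = 1.0
    topology: Optional[list[tuple[int, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1 or self.cells_per_branch < 1:
            raise ValueError("n_branches and cells_per_branch must be positive")
        if self.n_branches * self.genes_per_branch > self.n_genes:
            raise ValueError(
                f"{self.n_branches} branches x {self.genes_per_branch} genes "
                f"per branch exceed n_genes={self.n_genes}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.topology is None:
            if self.n_branches == 10:
                self.topology = list(DEFAULT_TOPOLOGY)
            else:
                # fallback: a chain rooted at branch 0
                self.topology = [(-1, 0.0)] + [
                    (b - 1, 1.0) for b in range(1, self.n_branches)
                ]
        if len(self.topology) != self.n_branches:
            raise ValueError("topology must list one (parent, position) per branch")
        if self.topology[0][0] != -1:
            raise ValueError("branch 0 must be the root (parent -1)")
        for b, (parent, pos) in enumerate(self.topology[1:], start=1):
            if not 0 <= parent < b:
                raise ValueError(
                    f"branch {b} has parent {parent}; parents must precede children "
                    "(acyclic, root first)"
                )
            if not 0.0 <= pos <= 1.0:
                raise ValueError(f"attachment position of branch {b} not in [0,1]")

    @property
    def n_cells(self) -> int:
        return self.n_branches * self.cells_per_branch


def _branch_bases(spec: TreeSpec) -> np.ndarray:
    """Expression state inherited by each branch at its attachment point."""
    bases = np.zeros((spec.n_branches, spec.n_genes))
    gpb = spec.genes_per_branch
    for b in range(1, spec.n_branches):
        parent, pos = spec.topology[b]
        bases[b] = bases[parent]
        bases[b, parent * gpb : (parent + 1) * gpb] += pos * spec.max_expression
    return bases


def generate_artificial_tree(spec: TreeSpec = TreeSpec()) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate the branching-tree benchmark; labels are branch indices."""
    rng = np.random.default_rng(spec.seed)
    bases = _branch_bases(spec)
    gpb = spec.genes_per_branch
    ramp = np.linspace(0.0, spec.max_expression, spec.cells_per_branch)
    mean = np.zeros((spec.n_cells, spec.n_genes))
    labels = np.zeros(spec.n_cells, dtype=int)
    for b in range(spec.n_branches):
        rows = slice(b * spec.cells_per_branch, (b + 1) * spec.cells_per_branch)
        mean[rows] = bases[b]
        mean[rows, b * gpb : (b + 1) * gpb] += ramp[:, None]
        labels[rows] = b
    values = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape) if spec.noise_sd > 0 else mean
    cell_ids = [f"b{labels[i]}_c{i}" for i in range(spec.n_cells)]
    gene_ids = [f"g{j}" for j in range(spec.n_genes)]
    return ExpressionMatrix(values, cell_ids, gene_ids, labels), labels


def generate_gaussian_clusters(
    n_clusters: int,
    n_per_cluster: int,
    dim: int,
    separation: float,
    seed: int = 0,
    sd: float = 1.0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Isotropic Gaussian blobs (per-coordinate noise ``sd``).

    For up to ``dim`` clusters the centers sit at ``separation`` along
    distinct coordinate axes; beyond that, on random directions of norm
    ``separation``.
    """
    if min(n_clusters, n_per_cluster, dim) < 1 or separation <= 0:
        raise ValueError("all generator arguments must be positive")
    rng = np.random.default_rng(seed)
    if n_clusters <= dim:
        centers = separation * np.eye(dim)[:n_clusters]
    else:
        dirs = rng.standard_normal((n_clusters, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        centers = separation * dirs
    n = n_clusters * n_per_cluster
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    values = centers[labels] + sd * rng.standard_normal((n, dim))
    return ExpressionMatrix(values, labels=labels), labels
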