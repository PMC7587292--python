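"""End-to-end pipeline runners binding preprocessing, affinities, training and
output files together, driven by a flat plain-text configuration.

``run_embed`` executes: read -> preprocess -> affinities (full or per-batch)
-> train (full-batch when no batch size is given, stochastic otherwise) and
writes the embedding CSV, the mapping file, the effective config and the
objective trace.  ``run_map`` applies a saved mapping to new cells with no
training.  One global seed fans out to per-component seeds by fixed offsets,
so toggling one stage leaves the others reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import preprocess
from .affinities import build_affinity_pair
from .containers import (
    Embedding,
    ExpressionMatrix,
    read_dense,
    read_embedding,
    read_mtx,
    write_embedding,
)
from .network import (
    TrainConfig,
    forward_map,
    init_network,
    load_mapping,
    save_mapping,
    train_full_batch,
)
from .stochastic import batch_affinities, partition_batches, train_stochastic

logger = logging.getLogger("eemap")

# fixed seed offsets per stochastic component
_SEED_PARTITION = 1
_SEED_NETWORK = 2
_SEED_TRAIN = 3


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of one embedding run."""

    input_path: str = ""
    input_format: str = "auto"          # auto | csv | tsv | mtx
    genes_in_rows: bool = False
    labels_path: Optional[str] = None
    # preprocessing
    log1p: bool = True
    n_top_genes: Optional[int] = 500
    standardize: bool = True
    n_pcs: Optional[int] = None
    # affinities
    affinity_mode: str = "entropic"     # entropic | gaussian
    affinity_parameter: float = 30.0    # perplexity or sigma
    lam: float = 1.0
    # model / training
    d: int = 2
    hidden_dims: tuple = (500, 100)
    activation: str = "tanh"
    learning_rate: float = 1e-3
    max_epochs: int = 500
    tol: float = 1e-5
    optimizer: str = "adam"
    batch_size: Optional[int] = None    # absent => full batch
    seed: int = 0
    # outputs
    output_embedding: str = "embedding.csv"
    output_model: str = "mapping.json"
    output_log: str = "run.log"

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (tuple, list)):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            kwargs[f.name] = _parse_field(f.name, val)
        return cls(**kwargs)


def _parse_field(name: str, val: str):
    optional_ints = {"n_top_genes", "n_pcs", "batch_size"}
    if val == "":
        return None if name in optional_ints or name == "labels_path" else ""
    if name == "hidden_dims":
        return tuple(int(x) for x in val.split(",") if x)
    if name in {"genes_in_rows", "log1p", "standardize"}:
        return val.lower() in {"1", "true", "yes"}
    if name in optional_ints or name in {"d", "max_epochs", "seed"}:
        return int(val)
    if name in {"affinity_parameter", "lam", "learning_rate", "tol"}:
        return float(val)
    return val


def load_matrix(cfg: RunConfig) -> ExpressionMatrix:
    fmt = cfg.input_format
    path = Path(cfg.input_path)
    if fmt == "auto":
        fmt = "mtx" if path.suffix.lower() == ".mtx" else "csv"
    if fmt == "mtx":
        return read_mtx(path, labels_path=cfg.labels_path)
    sep = "\t" if fmt == "tsv" else None
    return read_dense(path, sep=sep, genes_in_rows=cfg.genes_in_rows,
                      labels_path=cfg.labels_path)


def run_embed(cfg: RunConfig) -> tuple[Embedding, np.ndarray]:
    """Execute the full pipeline; writes embedding, model, config and trace."""
    stage = "read input"
    try:
        m = load_matrix(cfg)
        stage = "preprocess"
        m = preprocess.run_pipeline(
            m, log1p=cfg.log1p, n_top_genes=cfg.n_top_genes,
            standardize=cfg.standardize, n_pcs=cfg.n_pcs,
        )
        logger.info("preprocessed matrix: %d cells x %d features", m.n_cells, m.n_genes)

        tc = TrainConfig(
            learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
            tol=cfg.tol, seed=cfg.seed + _SEED_TRAIN, optimizer=cfg.optimizer,
            batch_size=cfg.batch_size,
        )
        net = init_network(m.n_genes, cfg.d, cfg.hidden_dims,
                           seed=cfg.seed + _SEED_NETWORK, activation=cfg.activation)

        if cfg.batch_size is None or cfg.batch_size >= m.n_cells:
            stage = "affinities"
            aff = build_affinity_pair(m, cfg.affinity_mode, cfg.affinity_parameter,
                                      cfg.lam)
            stage = "train (full batch)"
            net, emb, trace = train_full_batch(m, aff, net, tc)
        else:
            stage = "affinities (per batch)"
            part = partition_batches(m.n_cells, cfg.batch_size,
                                     seed=cfg.seed + _SEED_PARTITION)
            part = batch_affinities(m, part, cfg.affinity_mode,
                                    cfg.affinity_parameter, cfg.lam)
            stage = "train (stochastic)"
            net, emb, trace = train_stochastic(m, part, net, tc)

        stage = "write outputs"
        write_embedding(emb, cfg.output_embedding)
        save_mapping(net, cfg.output_model)
        cfg.to_file(str(cfg.output_embedding) + ".config")
        log_path = Path(cfg.output_log)
        with log_path.open("w") as fh:
            fh.write(f"epochs={len(trace)}\n")
            for i, v in enumerate(trace):
                fh.write(f"objective[{i}]={v!r}\n")
        logger.info("finished after %d epochs; final objective %g", len(trace), trace[-1])
        return emb, trace
    except Exception as e:
        raise RuntimeError(f"embedding pipeline failed at stage '{stage}': {e}") from e


def run_map(model_path: str | Path, cfg: RunConfig) -> Embedding:
    """Apply a saved mapping to new cells (out-of-sample extension)."""
    net = load_mapping(model_path)
    m = load_matrix(cfg)
    m = preprocess.run_pipeline(
        m, log1p=cfg.log1p, n_top_genes=cfg.n_top_genes,
        standardize=cfg.standardize, n_pcs=cfg.n_pcs,
    )
    if m.n_genes != net.input_dim:
        raise ValueError(
            f"input has {m.n_genes} features after preprocessing but the "
            f"mapping expects {net.input_dim}"
        )
    emb = forward_map(net, m)
    write_embedding(emb, cfg.output_embedding)
    return emb
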