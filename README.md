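# eemap — parametric elastic embedding for expression data

`eemap` visualizes single-cell (or bulk) expression matrices in two or three
dimensions with the **elastic embedding** (EE) energy, minimized not over
free per-cell coordinates but over the parameters of a feedforward network
that maps each expression profile to its embedded position. It targets
analysts who want t-SNE-like local resolution *plus*:

* **global structure** — EE's short-range Gaussian repulsion preserves
  inter-cluster geometry better than heavy-tailed neighbor embeddings;
* **scalability** — a mini-batch mode partitions the cells once, computes
  per-batch weight matrices offline, and averages per-batch gradients, so
  the N × N weight matrices never have to exist at full size;
* **generalizability** — the trained map embeds *new* cells with a forward
  pass, no re-optimization, and can be updated online with new batches.

## The objective

For embedded coordinates X = (x_1, …, x_N), attractive weights W⁺
(Gaussian or entropic affinities of the input profiles), repulsive weights
W⁻ (Euclidean distances), and trade-off λ:

    E(X) = Σ_{n≠m} w⁺_nm ‖x_n − x_m‖² + λ Σ_{n≠m} w⁻_nm exp(−‖x_n − x_m‖²)

With x_n = Net_θ(y_n), the closed-form coordinate gradient

    ∂E/∂x_n = 4 Σ_{m≠n} (w⁺_nm − λ w⁻_nm e^{−‖x_n−x_m‖²}) (x_n − x_m)

is backpropagated through the network: ∂E/∂θ = Σ_n (∂E/∂x_n)ᵀ ∂Net_θ(y_n)/∂θ.
See `docs/methods.md` for the full model description, defaults, and
numerical conventions.

## Worked example

Simulate the branching-tree benchmark (1,440 cells, 60 genes, 10 branches,
each branch ramping an exclusive 6-gene block), embed it, and score the
embedding by KNN cross-validation:

```python
from eemap import (TreeSpec, generate_artificial_tree, standardize_genes,
                   build_affinity_pair, init_network, train_full_batch,
                   TrainConfig, generalization_error)

m, labels = generate_artificial_tree(TreeSpec(seed=0))
m = standardize_genes(m)
aff = build_affinity_pair(m, mode="entropic", parameter=30.0, lam=1.0)
net = init_network(D=m.n_genes, d=2, hidden_dims=(500, 100), seed=0)
cfg = TrainConfig(learning_rate=1e-2, max_epochs=300, tol=1e-6, seed=0)
net, emb, trace = train_full_batch(m, aff, net, cfg)
res = generalization_error(emb, labels, k_max=40, n_folds=10, seed=0)
print(f"objective {trace[0]:.4f} -> {trace[-1]:.4f} in {len(trace)} epochs")
print(f"min 10-fold KNN CV error over K=1..40: {res.generalization_error:.4f}")
```

```
objective 0.6894 -> 0.0869 in 300 epochs
min 10-fold KNN CV error over K=1..40: 0.0625
```

The energy falls as the network learns the map; the final number says a
K-nearest-neighbor classifier working only in the 2-D embedding mislabels
about 6% of cells against the known branch labels — the branches are
resolved (2-D PCA on the same data scores ≈ 0.38). Training with
`batch_size=360` via `partition_batches` → `batch_affinities` →
`train_stochastic` gives a comparable score without ever forming the full
1440² weight matrices, and `forward_map(net, new_cells)` embeds unseen
cells into the same coordinate system.

The same pipeline is available from the shell:

```sh
eemap simulate-tree tree.csv --seed 0
eemap embed tree.csv --no-log1p --n-top-genes 0 --learning-rate 0.01 \
      --max-epochs 300 -o emb.csv --model map.json
eemap evaluate emb.csv labels.tsv -o report.json
eemap map map.json newcells.csv mapped.csv   # out-of-sample extension
```

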