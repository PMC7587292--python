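# Methods

## The model

`eemap` embeds N cells with D-dimensional expression profiles
y_1, …, y_N into d dimensions (usually d = 2) by minimizing the
elastic-embedding (EE) energy over the embedded coordinates
X = (x_1, …, x_N):

    E(X) = Σ_{n≠m} w⁺_nm ‖x_n − x_m‖²  +  λ Σ_{n≠m} w⁻_nm exp(−‖x_n − x_m‖²)

Both sums run over ordered pairs. The attractive weights W⁺ are high in the
high-dimensional neighborhood of each cell and pull those cells together in
the embedding; the repulsive weights W⁻ grow with high-dimensional
dissimilarity and push embedded points apart, but only at short embedded
range because of the Gaussian decay — which is what gives the energy a
finite-spread minimum and lets it preserve global structure better than
heavier-tailed neighbor embeddings. λ trades the two terms off.

Rather than optimizing the x_n freely, the parametric variant sets
x_n = Net_θ(y_n) for a feedforward network Net_θ : R^D → R^d and optimizes θ.
The coordinate gradient has the closed form

    ∂E/∂x_n = 4 Σ_{m≠n} (w⁺_nm − λ w⁻_nm exp(−‖x_n − x_m‖²)) (x_n − x_m)

and the parameter gradient follows by the chain rule,
∂E/∂θ = Σ_n (∂E/∂x_n)ᵀ ∂Net_θ(y_n)/∂θ, i.e. ordinary backpropagation with
∂E/∂x_n as the output-layer error signal. Because the map is parametric,
unseen cells are embedded by a single forward pass (out-of-sample extension),
and the model can be updated online by treating new cells as new batches.

A non-parametric baseline (`optimize_free_embedding`) minimizes E directly
over free coordinates with steepest descent and Armijo backtracking
(halving, c = 1e−4); every accepted step decreases the energy, so its
objective trace is monotone by construction.

## Weights

* **W⁺** — either fixed-bandwidth Gaussian affinities
  exp(−d²_nm/2σ²), or (default) *entropic affinities*: per-point conditional
  distributions p_{m|n} ∝ exp(−β_n d²_nm) whose bandwidths β_n are found by
  bisection so each row's entropy equals ln(perplexity), then symmetrized as
  (P + Pᵀ)/2. Bisection brackets β in [1e−20, 1e20], runs at most 200
  iterations to an entropy tolerance of 1e−5, and takes geometric midpoints
  while the bracket spans more than a decade (arithmetic after), which
  converges quickly across the bracket's 40 orders of magnitude. Distances
  are shifted per row by the nearest-neighbor distance before exponentiation;
  entropy is invariant to the shift and underflow is avoided. Default
  perplexity 30, the common neighbor-embedding operating point.
* **W⁻** — squared Euclidean distances by default; a `plain` (unsquared)
  dialect is available since both appear in the EE literature.
* **Normalization** — `build_affinity_pair` scales each matrix to unit total
  sum by default (`normalize="unit"`). The raw matrices live on wildly
  different scales (symmetrized conditional probabilities vs. squared
  distances of ~60 standardized features, a ratio of order 10⁵ at N ≈ 10³),
  so without a common scale λ = 1 effectively switches the attractive term
  off: on the tree benchmark the raw-scale embedding plateaus around
  0.17–0.21 minimum KNN-CV error, while unit-sum weights reach 0.06–0.08.
  Unit-sum normalization makes λ a genuine, data-size-independent trade-off;
  `normalize="none"` preserves the raw convention.

## Preprocessing

The chain is log(1+x) → keep the top-variance genes (default 500, unbiased
n−1 variances, ties broken by original column order) → per-gene
standardization (mean 0, sd 1, n−1 denominator) → optionally PCA to 50
scores for very wide matrices. The order is fixed; `run_pipeline` applies
exactly it. Zero-variance genes are an error in standardization rather than
silently dropped — the variance filter is the documented place to remove
them. PCA signs are fixed by making each component's largest-magnitude
loading positive, so scores are reproducible across platforms.

## Training

Full-batch: each epoch evaluates E and its θ-gradient on all cells and takes
one optimizer step (Adam by default, lr 1e−3; plain SGD exposed so the
gradient arithmetic is auditable). Stopping: `max_epochs` (default 500) or a
relative objective change below `tol` = 1e−5 across a 10-epoch window.

Stochastic (mini-batch): cells are partitioned once, before training, into
⌈N/batch_size⌉ random batches whose sizes differ by at most one (a balanced
split never creates a batch below 2 cells — with batch size 2 and odd N one
batch of 3 absorbs the remainder). Each batch's W⁺/W⁻ are computed offline
on its own submatrix. Every iteration averages the per-batch parameter
gradients over all batches (factor 1/|B|); any constant scale on that
average is folded into the learning rate. With one batch the scheme is
bitwise identical to full-batch training at equal θ — batch indices are kept
sorted, so the single batch is exactly the identity ordering and the same
gradient routine runs on the same arrays. A round-robin one-batch-per-step
mode and per-epoch repartitioning exist behind flags, both off by default.
The default batch size for large-data runs is 5,000 cells.

Network default: two tanh hidden layers of 500 and 100 units, identity
output layer, weights uniform on ±√(3/fan_in) (variance 1/fan_in), biases
zero, all seeded. The architecture is a replaceable default sized for
hundreds-to-thousands of input features; smaller problems use smaller
`hidden_dims`.

## Evaluation

Embedding quality is the minimum over K ∈ [1, 40] of the 10-fold
cross-validated KNN misclassification rate in the embedded space. Folds are
stratified (stability for small classes) and fixed across K so all K compete
on identical splits. Determinism: neighbor ties break toward the lower
training index (stable sort), vote ties toward the smaller class label.
The subsample experiment draws a seeded uniform subsample (10/25/50% are the
scales of interest), trains on it, maps *all* cells through the trained
network, and evaluates both embeddings; at scale 1.0 it reduces exactly to
the full run.

## The synthetic benchmarks

`generate_artificial_tree` builds a continuous branching trajectory:
10 branches × 144 cells (=1,440) over 60 genes, each branch owning an
exclusive 6-gene block (10 × 6 tile the 60 genes exactly) that ramps
linearly 0 → 1 along the branch; a child branch starts from its parent's
terminal state, so expression is continuous across attachments, and ancestor
blocks stay saturated while non-ancestral blocks stay at zero. Topology
default: a two-level tree (root → 3 children → 2 grandchildren each).
Additive Gaussian noise, sd 0.1 on the 0–1 ramp, keeps branches separable
while blurring boundaries — the intended difficulty of the benchmark. What
it does *not* emulate: count statistics (negative binomial dispersion,
dropout), library-size variation, batch effects; results on it bound method
behavior on clean trajectories only, not on real scRNA-seq noise.

`generate_gaussian_clusters` provides trivially separable blobs used to
assert exact-zero error paths.

## Benchmark protocol and problem sizes

The tree benchmark (scripts/acceptance.py and the end-to-end tests) uses the
default tree with data seed 0, standardized genes (the ramps are already on
a common 0–1 scale; log transformation is unnecessary and the noise makes
entries slightly negative), entropic affinities at perplexity 30, λ = 1,
d = 2, the default 500/100 network. Training runs Adam at lr 1e−2 for up to
300 epochs (tol 1e−6): on this problem the larger step reaches the same
plateau as the package default lr 1e−3/500 epochs in a third of the time
(min KNN-CV error 0.06 vs 0.07), and all benchmark results are medians over
three training seeds with the data seed held fixed. The stochastic run uses
4 batches of 360 cells. The 25%-subsample experiment trains on 360 cells
with the same settings.

## Numerical choices and degenerate inputs

* Squared-distance matrices are symmetrized exactly ((D + Dᵀ)/2), their
  diagonals zeroed, and clamped at 0 — AffinityPair asserts exact symmetry,
  not approximate.
* An all-duplicate batch has W⁻ ≡ 0; unit normalization skips the zero-sum
  division and the objective degenerates gracefully to the attractive term.
* Perplexity must lie in (1, N−1]; at the upper bound the conditional rows
  approach uniform and the bandwidth root sits at β → 0, which the bisection
  reaches within its entropy tolerance.
* The energy is invariant to translations and rotations of X, so its
  minimizers are equivalence classes; tests compare distances, errors, or
  invariants, never raw coordinates across runs.
* Mapping files are JSON with shortest-round-trip float serialization:
  save → load is bit-exact, and the format carries a version field.

## Known limitations

* Dense N × N weight matrices per batch: memory is O(batch_size²); the
  mini-batch path, not sparsity, is the scaling story. No k-NN-truncated or
  tree-approximated affinities.
* The trainer is CPU numpy; per-epoch cost is O(N² d + N·P) for P network
  parameters. Millions of cells require the mini-batch path and patience.
* Adam's trajectory, and therefore the embedding, depends on the training
  seed; only evaluation metrics are compared across seeds.
* The free-embedding baseline uses first-order descent; second-order EE
  solvers (spectral direction / partial Hessian) are out of scope.
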