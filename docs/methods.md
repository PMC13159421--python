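# Methods

This note documents the model, the completions we had to make where the
method leaves details open, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Model and assumptions

The pipeline assumes that (i) spatial domains are locally contiguous, so
a spot's two-hop spatial neighborhood is mostly same-domain and graph
convolution acts as a domain-preserving denoiser; and (ii) expression
clusters, even unsupervised and over-segmented ones, are informative
about domains, so pulling embeddings toward their expression-cluster
prototypes sharpens domain separation. The spot graph is built from
coordinates only; expression similarity never creates edges.

The per-spot encoder runs on the *induced* two-hop subgraph: node
degrees in the normalization are subgraph degrees, and the embedding is
the center-node row of the final layer, not a pooled readout. This makes
the representation strictly local (expression at hop distance ≥ 3 cannot
affect a spot) and makes batched and per-spot encoding bit-identical.

### Graph similarity

Spot similarity for neighbor selection is negative Euclidean distance
between coordinate vectors. A raw inner-product score over coordinates
is implemented behind `similarity="inner-product"` for comparison, but
it is not a proximity measure — it ranks spots far from the coordinate
origin as "most similar" regardless of location — so proximity is the
default and the inner-product mode exists only for fidelity experiments.

### Soft K-means completions

The soft assignment and centroid update are standard; three details are
our completions and are therefore marked as package decisions:

- **Variance estimator**: responsibility-weighted isotropic variance,
  `σ_k² = Σ_i p_{i,k}‖x_i−μ_k‖² / (g·Σ_i p_{i,k})`, floored at `1e-6`
  to prevent collapse onto duplicated points.
- **Initialization**: k-means++ on the (optionally PCA-reduced) input
  with the run seed.
- **Convergence**: max absolute responsibility change `< 1e-5`, cap of
  300 iterations. Empty clusters are re-seeded at the point with the
  lowest maximum responsibility so all `K` clusters stay available for
  N-way episode sampling.

With assignments hardened each step and a frozen common variance the
procedure is exactly Lloyd's K-means; the tests exploit this as an
oracle.

### Episode construction and losses

Episodes use hard pseudo-labels (argmax responsibilities), not the soft
vectors, for both sampling and the losses; "up to" semantics apply when
a class has fewer than `M` members or the query pool is small. The query
probability distribution is not fully specified by the loss definitions,
so we use the minimal completion consistent with the episode structure:
a softmax over query–prototype dot products with the same temperature τ
as the contrastive term; it introduces no extra parameters. Embeddings
enter all similarities un-normalized (no l2-normalization).

The contrastive denominator sums over the *other* classes only
(`k ≠ i`). A consequence worth stating plainly: the loss is unbounded
below — scaling all embeddings by `c > 1` decreases it without limit —
so the optimizer will eventually inflate embedding norms rather than
improve structure. Training therefore operates in an early-stopping
regime controlled by feature scale and learning rate (next section).
Per episode we take one joint Adam step on `L_T`; a sequential mode (a
contrastive step followed by a classification step) is available via
`sequential_steps=True` and gives the same first-order behavior.

## Parameters, units, defaults

| parameter | default | notes |
|---|---|---|
| `k_neighbors` | 6 | hexagonal Visium-like neighborhoods |
| `k_clusters` (K) | 10 | pseudo-label clusters; robust for K ≥ 10 |
| `d_h` | 64 | embedding width; hidden layer 128, ReLU, linear output |
| `tau` (τ) | 0.5 | temperature; moderate values 0.5–1 work best |
| `alpha` (α) | 0.5 | contrastive/classification balance |
| `n_way, m_shot, q_query` | 5, 5, 15 | episode shape |
| `episodes_per_epoch, n_epochs` | 50, 40 | 2000 episodes total |
| `learning_rate` | 1e-5 | see below |
| `standardize_features` | True | per-gene z-score before the encoder |
| `split_fractions` | 0.8/0.1/0.1 | largest-remainder rounding |
| imputation ridge `l2` | 1e-3 | intercept unpenalized |
| LISI `perplexity` | 30 | conventional neighborhood scale |

**Learning rate and feature scale.** Because the contrastive objective
has no finite minimum, the learning rate is the de facto early-stopping
knob: clustering quality rises with the learning rate up to a threshold
and collapses above it once norm inflation dominates (on the reference
benchmark, ARI falls from ≈ 0.99 to ≈ 0.43 between 1e-5 and 1e-3 at the
default 2000 episodes). We standardize each gene to zero mean and unit
variance before encoding — the usual ST preprocessing step — so that
initial dot products are O(1) and the default `learning_rate = 1e-5`
keeps the whole default schedule inside the well-behaved regime.
Pseudo-labels are computed on the unstandardized expression matrix
(optionally PCA-reduced to 50 components); the imputation head maps back
to the original expression units.

**Pseudo-label refresh.** Pseudo-labels are computed once before
training. `refresh_pseudo_labels=True` re-clusters the current
embeddings at each epoch; it is off by default because clustering is a
preliminary weak-supervision step, not part of the episodic loop.

## Synthetic data

The generator emulates the inputs of a spot-level ST experiment: spots
on a 2-D lattice (or uniform at random), each carrying exactly one
planted domain label (horizontal bands by y-quantile, or Voronoi blobs)
and one batch label. Expression is
`clip(μ_domain + N(0, noise_sd²) + batch_shift, 0) · Bernoulli(1−dropout)`,
with per-gene domain means drawn from `effect_size · Gamma(2, ½)` so the
average expression level equals `effect_size` and means are bounded away
from zero (keeping the clip bias small). Defaults: 600 spots, 60 genes,
4 domains, `effect_size 1`, `noise_sd 1`, `dropout 0.3` (a realistic ST
sparsity level), one batch.

What it does **not** emulate: count-distribution realism (no negative
binomial), mean–variance coupling, spatially smooth within-domain
gradients, cell-type mixtures within spots, or histology. Passing the
recovery benchmarks therefore shows that the pipeline correctly
exploits spatial contiguity and cluster structure under dropout noise —
not that it matches any particular published accuracy on real tissue.

## Numerical choices

- All softmax-type quantities (responsibilities, contrastive
  denominator, query probabilities) use log-sum-exp stabilization;
  query probabilities are clamped at `1e-12` before logs.
- Gradients of `L_T` — through the prototypes back to the support set
  and through each subgraph GCN — are derived by hand and checked
  against central finite differences (max relative error < 1e-4 is
  asserted; measured ≈ 1e-7).
- k-NN ties at equal distance break toward the lower spot index, making
  graphs on lattices deterministic; the edge set is the union over both
  endpoints' selections, so every spot keeps degree ≥ k.
- Largest-remainder rounding makes the 80/10/10 split sizes exact
  whenever `C` is divisible by 10.
- Degenerate inputs: a single-spot graph has no edges and its normalized
  subgraph adjacency is the scalar 1; `K = 1` soft K-means yields
  all-ones responsibilities; single-category LISI is exactly 1; an
  unpenalized ridge fit on zero-variance embeddings raises instead of
  silently pseudo-inverting.
- Determinism: every stochastic step (generator, splits, k-means++
  seeding, encoder init, episode sampling) draws from a
  `numpy.random.Generator` seeded from the run seed; two runs with the
  same config are bitwise identical.

## Evaluation protocol

`run_multi_seed` repeats the pipeline per seed: re-split 80/10/10,
re-initialize, sample episodes from the training split only, embed all
spots, cluster into the annotation-level number of domains, and score
ARI/NMI/ACC/purity/homogeneity on all spots (mean over seeds is the
dataset-level summary). ACC uses Hungarian cluster-to-class assignment;
NMI uses arithmetic-mean normalization; homogeneity uses natural-log
entropies with 0·log 0 = 0. Imputation is scored on a random held-out
entry mask: the head is refitted per gene on observed entries only and
PCC/L1/RMSE are computed on the masked entries. Cross-method comparison
uses a paired two-sided Wilcoxon signed-rank test over dataset-level
means.

The acceptance script uses 600 spots, 60 genes, 4 domains, and 5 seeds
throughout — sizes at which every stage of the pipeline (graph, episodic
training, clustering, imputation, LISI) is exercised end to end while a
full multi-seed run stays interactive on a laptop CPU.

## Known limitations

- The unbounded contrastive objective means very long schedules or
  aggressive learning rates degrade embeddings; there is no internal
  early-stopping monitor beyond the divergence abort on non-finite loss.
- The GAT/attention encoder variant and three-hop neighborhoods are
  deliberately unsupported; the encoder interface accepts alternative
  propagation rules for future variants.
- Harmony-style batch correction is not reimplemented; LISI scoring
  accepts externally corrected embeddings.
- No HDF5/h5ad reader; dense CSV/TSV and MatrixMarket triplets only.
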