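# gatorst

Contrastive meta-learning for spatial transcriptomics (ST).

Spatial transcriptomics assays measure a gene expression vector at each
of thousands of spatially located capture spots. A central analysis task
is **spatial domain identification**: partitioning spots into contiguous
tissue regions (cortical layers, tumor regions, …) of coherent
expression, despite high dimensionality, sparsity, and technical noise.
`gatorst` learns a low-dimensional spot representation that fuses the
spatial neighborhood structure with global expression patterns, and
applies it to domain identification, gene expression imputation,
trajectory-input export, and batch-integration scoring. It is aimed at
computational biologists working with Visium-, Stereo-seq-, or
Slide-seq-style data, or with synthetic benchmarks.

## Method

Given expression `X ∈ R^{C×g}` and spot locations `z_i`:

1. **Spot–spot graph.** A k-NN graph `A ∈ {0,1}^{C×C}` over spatial
   coordinates (default `k = 6`, matching a hexagonal Visium
   neighborhood; union-symmetrized, lower-index tie-break).
2. **Two-hop subgraph encoding.** Each spot `v` is encoded by a GCN over
   its induced two-hop subgraph `N_v = {u | 1 ≤ d(v,u) ≤ 2}` with
   Kipf-style normalization `D̃^{-1/2}(A+I)D̃^{-1/2}`, reading out the
   center row: `h_v ∈ R^{d_h}`. The implementation is pure numpy with
   hand-derived, finite-difference-validated backpropagation.
3. **Pseudo-labels.** Variance-aware soft K-means on expression
   (`K = 10` by default) gives responsibilities
   `p_{i,k} ∝ exp(−½‖x_i−μ_k‖²/σ_k²)`; the argmax is the hard
   pseudo-label `y_i`.
4. **Episodic training.** Each episode samples an N-way M-shot support
   set `S` and disjoint query set `Q` from the pseudo-labels. With class
   prototypes `ĥ_i` (support means) the objective is

   ```
   L_CT = −(1/NM) Σ_{i,j} log[ exp(h_i^j·ĥ_i/τ) / Σ_{k≠i} exp(h_i^j·ĥ_k/τ) ]
   L_CE = −(1/Q)  Σ_i log p_i(y_i),   p_i = softmax_j(h'_i·ĥ_j/τ)
   L_T  = α·L_CT + (1−α)·L_CE
   ```

   with one Adam step per episode, embeddings un-normalized, and
   temperature `τ = 0.5` by default.
5. **Downstream.** K-means on `H` for domains (objective
   `L_cluster = Σ_i ‖h_i − μ_{z_i}‖²`); a closed-form ridge head
   `X̂ = H W_X + b_X` for imputation; CSV export for UMAP/PAGA;
   per-spot LISI with the normalizations
   `ncLISI = (N_celltypes − cLISI)/(N_celltypes − 1)` and
   `niLISI = (iLISI − 1)/(N_datasets − 1)`.

See `docs/methods.md` for assumptions, parameter choices, and
limitations.

## Worked example

```python
from gatorst import (RunConfig, SyntheticSpec, build_knn_graph,
                     clustering_metrics, generate_dataset,
                     identify_domains, train)

spec = SyntheticSpec(n_spots=400, n_genes=40, n_domains=4,
                     effect_size=3.0, noise_sd=1.0, seed=0)
dataset, _ = generate_dataset(spec)          # planted 4-band tissue
graph = build_knn_graph(dataset.coordinates, k=6)
result = train(dataset, graph, RunConfig(seed=0, n_epochs=10))
domains = identify_domains(result.embeddings, 4, seed=0)
scores = clustering_metrics(domains.assignments, dataset.true_labels)
print(f"first-episode loss L_T = {result.log[0]['loss_combined']:.3f}")
print(f"last-episode  loss L_T = {result.log[-1]['loss_combined']:.3f}")
print(f"ARI  = {scores.ari:.3f}")
```

Output:

```
first-episode loss L_T = 1.767
last-episode  loss L_T = -3.033
ARI  = 1.000
```

The training loss falls as embeddings align with their pseudo-label
prototypes, and K-means on the learned embeddings recovers the four
planted domains exactly (ARI = 1); K-means on the raw, dropout-corrupted
expression matrix does not.

The same pipeline is available from the shell:

```sh
gatorst simulate --spec spec.toml --out data/
gatorst run --expression data/expression.csv --coords data/coordinates.csv \
            --labels data/labels.csv --config cfg.toml --out run/
gatorst evaluate --pred run/domains.csv --truth data/labels.csv
gatorst impute --expression data/expression.csv --coords data/coordinates.csv \
               --mask-rate 0.2 --out imp/
```

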