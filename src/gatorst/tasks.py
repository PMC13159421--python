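"""Downstream applications of the learned spot embeddings.

* Spatial domain identification: K-means on the embedding matrix H,
  minimizing L_cluster = sum_i ||h_i - mu_{z_i}||^2.
* Gene expression imputation: a post hoc linear head X_hat = H W_X + b_X
  fitted by closed-form ridge regression (per gene, optionally excluding
  masked entries), not jointly optimized with the encoder.
* Trajectory/batch export: embeddings + cluster labels written as CSV for
  external UMAP / PAGA / Harmony tooling.
* Integration scoring: per-spot LISI (local inverse Simpson index of a
  label distribution over a perplexity-tuned Gaussian neighborhood) and
  the normalized summaries
      ncLISI = (N_celltypes - cLISI) / (N_celltypes - 1)
      niLISI = (iLISI - 1) / (N_datasets - 1),
  both in [0, 1], higher better.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors


@dataclass
class DomainResult:
    assignments: np.ndarray       # C ints in {0..K-1}
    centroids: np.ndarray         # K x d_h
    objective: float              # sum of squared distances to assigned centroid


@dataclass
class ImputationHead:
    weights: np.ndarray           # d_h x g
    bias: np.ndarray              # g


@dataclass
class LisiScores:
    clisi_per_spot: np.ndarray
    ilisi_per_spot: np.ndarray
    clisi: float
    ilisi: float
    nclisi: float
    nilisi: float
    n_celltypes: int
    n_datasets: int


def identify_domains(H: np.ndarray, n_domains: int, seed: int = 0,
                     n_restarts: int = 10) -> DomainResult:
    """Partition spots into spatial domains by K-means on the embeddings.

    Lloyd iterations with k-means++ seeding, best of ``n_restarts``
    restarts; deterministic per seed.
    """
    H = np.asarray(H, float)
    if n_domains > H.shape[0]:
        raise ValueError("n_domains cannot exceed the number of spots")
    km = KMeans(n_clusters=n_domains, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(H)
    objective = float(((H - km.cluster_centers_[labels]) ** 2).sum())
    return DomainResult(assignments=labels, centroids=km.cluster_centers_,
                        objective=objective)


def fit_imputation_head(
    H: np.ndarray,
    X: np.ndarray,
    l2: float = 1e-3,
    mask: np.ndarray | None = None,
) -> ImputationHead:
    """Closed-form ridge fit of the linear imputation head.

    Minimizes ||X - (H W + b)||^2 + l2 ||W||^2 (the intercept is not
    penalized).  ``mask`` marks held-out entries (True = excluded from
    the fit), enabling masked-entry evaluation; genes with a mask share
    no information, so each masked gene is fitted on its own observed
    rows.
    """
    H = np.asarray(H, float)
    X = np.asarray(X, float)
    if H.shape[0] != X.shape[0]:
        raise ValueError("H and X must have equal row counts")
    d, g = H.shape[1], X.shape[1]

    def _solve(Hs: np.ndarray, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h_mean = Hs.mean(axis=0)
        x_mean = Xs.mean(axis=0)
        Hc = Hs - h_mean
        A = Hc.T @ Hc + l2 * np.eye(d)
        if l2 == 0 and np.linalg.cond(A) > 1e12:
            raise LinAlgError("degenerate embeddings: ridge penalty required")
        W = solve(A, Hc.T @ (Xs - x_mean), assume_a="pos" if l2 > 0 else "gen")
        return W, x_mean - h_mean @ W

    if mask is None:
        W, b = _solve(H, X)
        return ImputationHead(weights=W, bias=b)
    mask = np.asarray(mask, bool)
    W = np.empty((d, g))
    b = np.empty(g)
    for j in range(g):
        rows = ~mask[:, j]
        if rows.sum() < 2:
            raise ValueError(f"gene {j} has fewer than 2 observed entries")
        Wj, bj = _solve(H[rows], X[rows, j:j + 1])
        W[:, j] = Wj[:, 0]
        b[j] = bj[0]
    return ImputationHead(weights=W, bias=b)


def impute_expression(H: np.ndarray, head: ImputationHead) -> np.ndarray:
    """Project embeddings back to expression space: X_hat = H W_X + b_X."""
    H = np.asarray(H, float)
    if H.shape[1] != head.weights.shape[0]:
        raise ValueError(
            f"embedding dimension {H.shape[1]} does not match head "
            f"input {head.weights.shape[0]}"
        )
    return H @ head.weights + head.bias


def compute_lisi(
    embedding: np.ndarray,
    labels: np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-5,
) -> np.ndarray:
    """Per-spot local inverse Simpson index of ``labels`` in ``embedding``.

    For each spot, neighbor weights follow a Gaussian kernel whose
    bandwidth is tuned by binary search so the weight entropy matches
    log(perplexity); the score is 1 / sum_c p_c^2 over the weighted label
    distribution.  Scores range from 1 (pure neighborhood) to the number
    of categories (ideal mixing).
    """
    E = np.asarray(embedding, float)
    labels = np.asarray(labels)
    cats, enc = np.unique(labels, return_inverse=True)
    n, n_cats = E.shape[0], len(cats)
    if n_cats == 1:
        return np.ones(n)
    k = min(int(3 * perplexity), n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    dist, idx = nn.kneighbors(E)
    dist, idx = dist[:, 1:], idx[:, 1:]          # drop self
    d2 = dist ** 2
    target = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * (d2[i] - d2[i].min()))
            wsum = w.sum()
            p = w / wsum
            entropy = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(entropy - target) < tol:
                break
            if entropy > target:               # too flat: sharpen
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        probs = np.bincount(enc[idx[i]], weights=p, minlength=n_cats)
        scores[i] = 1.0 / np.maximum((probs ** 2).sum(), 1e-300)
    return scores


def normalize_lisi(
    clisi: float, ilisi: float, n_celltypes: int, n_datasets: int
) -> tuple[float, float]:
    """Map mean cLISI/iLISI onto [0, 1] (higher = better on both axes)."""
    if n_celltypes < 2 or n_datasets < 2:
        raise ValueError("need at least 2 cell types and 2 datasets")
    nclisi = (n_celltypes - clisi) / (n_celltypes - 1)
    nilisi = (ilisi - 1.0) / (n_datasets - 1)
    return float(np.clip(nclisi, 0.0, 1.0)), float(np.clip(nilisi, 0.0, 1.0))


def lisi_report(
    embedding: np.ndarray,
    celltype_labels: np.ndarray,
    batch_labels: np.ndarray,
    perplexity: float = 30.0,
) -> LisiScores:
    """cLISI over cell-type labels, iLISI over batch labels, plus their
    normalized summaries."""
    cl = compute_lisi(embedding, celltype_labels, perplexity)
    il = compute_lisi(embedding, batch_labels, perplexity)
    n_ct = len(np.unique(celltype_labels))
    n_ds = len(np.unique(batch_labels))
    ncl, nil = normalize_lisi(float(cl.mean()), float(il.mean()), n_ct, n_ds)
    return LisiScores(
        clisi_per_spot=cl, ilisi_per_spot=il,
        clisi=float(cl.mean()), ilisi=float(il.mean()),
        nclisi=ncl, nilisi=nil,
        n_celltypes=n_ct, n_datasets=n_ds,
    )


def export_for_trajectory(
    H: np.ndarray,
    assignments: np.ndarray,
    out_path: str | Path,
    spot_ids: list[str] | None = None,
) -> Path:
    """Write embeddings + cluster labels as one CSV for external
    trajectory-inference tooling (UMAP/PAGA); no trajectory is computed."""
    H = np.asarray(H, float)
    if len(assignments) != H.shape[0]:
        raise ValueError("assignments and H must have equal row counts")
    out_path = Path(out_path)
    ids = spot_ids or [f"spot{i}" for i in range(H.shape[0])]
    df = pd.DataFrame(H, index=ids, columns=[f"h{i}" for i in range(H.shape[1])])
    df.insert(0, "cluster", np.asarray(assignments))
    df.to_csv(out_path, index_label="spot_id")
    return out_path
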