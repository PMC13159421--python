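"""Variance-aware soft K-means pseudo-labeling on expression profiles.

Each spot i gets a soft cluster membership

    p_{i,k} = exp(-1/2 ||x_i - mu_k||^2 / sigma_k^2)
              / sum_j exp(-1/2 ||x_i - mu_j||^2 / sigma_j^2)

and centroids are updated as responsibility-weighted means,

    mu_k = sum_i p_{i,k} x_i / sum_i p_{i,k},

iterating to convergence.  The hard pseudo-label of spot i is
y_i = argmax_k p_{i,k}; these serve as weak supervision for episodic
training.  The per-cluster variance is the responsibility-weighted
isotropic estimate sigma_k^2 = sum_i p_{i,k} ||x_i - mu_k||^2 / (g sum_i p_{i,k}),
floored at 1e-6 to prevent collapse; centroids are seeded with k-means++.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA

VARIANCE_FLOOR = 1e-6


@dataclass
class PseudoLabels:
    responsibilities: np.ndarray   # C x K, row-stochastic
    centroids: np.ndarray          # K x g
    variances: np.ndarray          # K, >= VARIANCE_FLOOR
    hard_labels: np.ndarray        # C ints in {0..K-1}
    n_iterations_run: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def soft_assign(
    X: np.ndarray, centroids: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    """Row-stochastic soft assignments, computed with log-sum-exp stabilization."""
    X = np.asarray(X, float)
    centroids = np.asarray(centroids, float)
    variances = np.asarray(variances, float)
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    d2 = (
        (X ** 2).sum(1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids ** 2).sum(1)[None, :]
    )
    np.clip(d2, 0.0, None, out=d2)
    logits = -0.5 * d2 / variances[None, :]
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def update_centroids(X: np.ndarray, responsibilities: np.ndarray) -> np.ndarray:
    """Responsibility-weighted means; near-empty clusters are re-seeded at
    the point currently worst explained (lowest max responsibility)."""
    X = np.asarray(X, float)
    R = np.asarray(responsibilities, float)
    if R.shape[0] != X.shape[0]:
        raise ValueError("responsibilities and X must have equal row counts")
    mass = R.sum(axis=0)
    centroids = np.empty((R.shape[1], X.shape[1]))
    ok = mass > 1e-12
    centroids[ok] = (R.T[ok] @ X) / mass[ok, None]
    if not ok.all():
        worst = np.argsort(R.max(axis=1))
        for rank, k in enumerate(np.flatnonzero(~ok)):
            centroids[k] = X[worst[rank % len(worst)]]
    return centroids


def _update_variances(X: np.ndarray, R: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    g = X.shape[1]
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2) \
        if X.shape[0] * centroids.shape[0] * g < 2_000_000 else None
    if d2 is None:
        d2 = (
            (X ** 2).sum(1)[:, None]
            - 2.0 * X @ centroids.T
            + (centroids ** 2).sum(1)[None, :]
        )
        np.clip(d2, 0.0, None, out=d2)
    mass = R.sum(axis=0)
    var = np.where(mass > 1e-12, (R * d2).sum(axis=0) / (g * np.maximum(mass, 1e-12)), 1.0)
    return np.maximum(var, VARIANCE_FLOOR)


def fit_soft_kmeans(
    X: np.ndarray,
    n_clusters: int,
    max_iter: int = 300,
    tol: float = 1e-5,
    seed: int = 0,
    init_centroids: np.ndarray | None = None,
    update_variance: bool = True,
    fixed_variance: float = 1.0,
    harden: bool = False,
    pca_components: int | None = None,
) -> PseudoLabels:
    """Alternate soft assignment / centroid update / variance update until
    the largest responsibility change drops below ``tol``.

    ``harden=True`` replaces the soft assignments with their one-hot
    argmax each iteration; with ``update_variance=False`` and a common
    ``fixed_variance`` this reduces exactly to Lloyd's K-means.
    ``pca_components`` optionally projects X to its leading principal
    components first (labels are computed in the reduced space).
    """
    X = np.asarray(X, float)
    C = X.shape[0]
    if n_clusters > C:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of points {C}")
    if pca_components is not None and pca_components < min(X.shape):
        X = PCA(n_components=pca_components, random_state=seed).fit_transform(X)
    if init_centroids is not None:
        centroids = np.asarray(init_centroids, float).copy()
    else:
        centroids, _ = kmeans_plusplus(
            X, n_clusters, random_state=np.random.RandomState(seed)
        )
    variances = np.full(n_clusters, float(fixed_variance))
    R_prev = None
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        R = soft_assign(X, centroids, variances)
        if harden:
            hard = np.argmax(R, axis=1)
            R = np.zeros_like(R)
            R[np.arange(C), hard] = 1.0
        centroids = update_centroids(X, R)
        if update_variance:
            variances = _update_variances(X, R, centroids)
        if R_prev is not None and np.max(np.abs(R - R_prev)) < tol:
            converged = True
            R_prev = R
            break
        R_prev = R
    R = soft_assign(X, centroids, variances)
    if harden:
        hard = np.argmax(R, axis=1)
        R = np.zeros_like(R)
        R[np.arange(C), hard] = 1.0
    return PseudoLabels(
        responsibilities=R,
        centroids=centroids,
        variances=variances,
        hard_labels=np.argmax(R, axis=1),
        n_iterations_run=iteration,
        converged=converged,
    )
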