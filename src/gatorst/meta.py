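"""Episodic contrastive meta-learning over pseudo-labeled spots.

Training proceeds in episodes.  Each episode samples an N-way, M-shot
support set S (N pseudo-label classes, up to M spots each) and a query
set Q of up to Q further spots from the same classes, disjoint from S.
Support embeddings define class prototypes (their per-class means), and
two losses are combined:

    L_CT = -(1/|S|) sum_{i,j} log[ exp(h_i^j . hhat_i / tau)
                                   / sum_{k != i} exp(h_i^j . hhat_k / tau) ]
    L_CE = -(1/|Q|) sum_i log p_i(y_i),   p_i = softmax_j(h'_i . hhat_j / tau)
    L_T  = alpha * L_CT + (1 - alpha) * L_CE

Note the contrastive denominator runs over the *other* classes only
(k != i), and embeddings enter the dot products un-normalized — no
l2-normalization is applied, to preserve magnitude information.  The
temperature tau sets the sharpness of the similarity distribution.

One Adam step is taken per episode on the joint objective L_T (a
sequential two-step mode — contrastive step, then classification step —
is available via ``sequential_steps``).  All gradients are analytic,
flowing through the prototypes back to the support embeddings and
through each spot's subgraph GCN to the encoder weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .datasets import RunConfig, SpotDataset
from .encoder import (EncoderParams, batch_for_spots, build_subgraph_cache,
                      encode_all, init_params)
from .graph import SpotGraph
from .pseudolabels import PseudoLabels, fit_soft_kmeans

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-12


@dataclass
class Episode:
    """One meta-training task: support and query node sets."""

    support_nodes: np.ndarray     # |S| spot indices
    support_classes: np.ndarray   # |S| positions into class_list
    query_nodes: np.ndarray       # |Q| spot indices, disjoint from support
    query_classes: np.ndarray     # |Q| positions into class_list
    class_list: np.ndarray        # the N sampled pseudo-label ids


@dataclass
class LossBreakdown:
    contrastive: float
    classification: float
    combined: float
    prototypes: np.ndarray


def sample_episode(
    hard_labels: np.ndarray,
    n_way: int,
    m_shot: int,
    q_query: int,
    rng: np.random.Generator,
    candidates: np.ndarray | None = None,
) -> Episode:
    """Sample one episode from the pseudo-labeled spots.

    ``candidates`` optionally restricts sampling to a subset of spots
    (e.g. the training split).  Classes are drawn without replacement
    among those with at least one member; "up to" semantics apply when a
    class has fewer than ``m_shot`` members or the query pool is small.
    """
    if n_way < 2:
        raise ValueError("episodes need n_way >= 2 (contrastive denominator)")
    hard_labels = np.asarray(hard_labels)
    pool = np.arange(len(hard_labels)) if candidates is None else np.asarray(candidates)
    labels = hard_labels[pool]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < n_way:
        raise ValueError(
            f"only {len(classes)} nonempty classes available, need {n_way}"
        )
    chosen = rng.choice(classes, size=n_way, replace=False)
    support_nodes, support_classes = [], []
    leftover_nodes, leftover_classes = [], []
    for pos, c in enumerate(chosen):
        members = pool[labels == c]
        members = rng.permutation(members)
        take = min(m_shot, len(members))
        support_nodes.extend(members[:take])
        support_classes.extend([pos] * take)
        leftover_nodes.extend(members[take:])
        leftover_classes.extend([pos] * (len(members) - take))
    leftover_nodes = np.asarray(leftover_nodes, dtype=int)
    leftover_classes = np.asarray(leftover_classes, dtype=int)
    if q_query > 0 and len(leftover_nodes) > 0:
        sel = rng.choice(len(leftover_nodes), size=min(q_query, len(leftover_nodes)),
                         replace=False)
        query_nodes, query_classes = leftover_nodes[sel], leftover_classes[sel]
    else:
        query_nodes = np.empty(0, dtype=int)
        query_classes = np.empty(0, dtype=int)
    return Episode(
        support_nodes=np.asarray(support_nodes, dtype=int),
        support_classes=np.asarray(support_classes, dtype=int),
        query_nodes=query_nodes,
        query_classes=query_classes,
        class_list=np.asarray(chosen),
    )


def class_prototypes(
    support_embeddings: np.ndarray, support_classes: np.ndarray, n_way: int
) -> np.ndarray:
    """Per-class arithmetic means of the support embeddings."""
    H = np.asarray(support_embeddings, float)
    cs = np.asarray(support_classes, int)
    protos = np.empty((n_way, H.shape[1]))
    for i in range(n_way):
        mask = cs == i
        if not mask.any():
            raise ValueError(f"class position {i} has no support embeddings")
        protos[i] = H[mask].mean(axis=0)
    return protos


def contrastive_loss(
    support_embeddings: np.ndarray,
    support_classes: np.ndarray,
    tau: float,
    prototypes: np.ndarray | None = None,
) -> float:
    """Prototype contrastive loss over the support set (denominator over
    the other classes only), computed with log-sum-exp stabilization."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    H = np.asarray(support_embeddings, float)
    cs = np.asarray(support_classes, int)
    n_way = int(cs.max()) + 1 if prototypes is None else prototypes.shape[0]
    if n_way < 2:
        raise ValueError("contrastive loss needs at least 2 classes")
    if prototypes is None:
        prototypes = class_prototypes(H, cs, n_way)
    sims = H @ prototypes.T / tau                      # |S| x N
    pos = sims[np.arange(len(cs)), cs]
    masked = sims.copy()
    masked[np.arange(len(cs)), cs] = -np.inf           # k != i only
    return float(-(pos - logsumexp(masked, axis=1)).mean())


def query_class_probabilities(
    query_embeddings: np.ndarray, prototypes: np.ndarray, tau: float
) -> np.ndarray:
    """Softmax over prototype similarities: p_i(j) ∝ exp(h'_i . hhat_j / tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    sims = np.atleast_2d(np.asarray(query_embeddings, float)) @ prototypes.T / tau
    return softmax(sims, axis=1)


def classification_loss(probabilities: np.ndarray, query_classes: np.ndarray) -> float:
    """Mean cross-entropy of the query predictions against one-hot labels."""
    P = np.atleast_2d(np.asarray(probabilities, float))
    cq = np.asarray(query_classes, int)
    if P.shape[0] == 0:
        raise ValueError("empty query set")
    picked = P[np.arange(len(cq)), cq]
    if np.any(picked <= 0):
        logger.warning("query probability of true class hit zero; clamping")
        picked = np.maximum(picked, PROB_CLAMP)
    return float(-np.log(picked).mean())


def combined_loss(l_ct: float, l_ce: float, alpha: float) -> float:
    """L_T = alpha * L_CT + (1 - alpha) * L_CE."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    return alpha * l_ct + (1.0 - alpha) * l_ce


def episode_losses_and_grads(
    support_embeddings: np.ndarray,
    support_classes: np.ndarray,
    query_embeddings: np.ndarray,
    query_classes: np.ndarray,
    tau: float,
    alpha: float,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Losses of one episode and the gradients of L_T with respect to the
    support and query embeddings (prototype dependence included)."""
    Hs = np.asarray(support_embeddings, float)
    cs = np.asarray(support_classes, int)
    Hq = np.asarray(query_embeddings, float).reshape(-1, Hs.shape[1])
    cq = np.asarray(query_classes, int)
    n_way = int(cs.max()) + 1
    S = len(cs)
    protos = class_prototypes(Hs, cs, n_way)
    counts = np.bincount(cs, minlength=n_way).astype(float)

    # --- contrastive term ---
    sims = Hs @ protos.T / tau
    pos = sims[np.arange(S), cs]
    masked = sims.copy()
    masked[np.arange(S), cs] = -np.inf
    lse = logsumexp(masked, axis=1)
    l_ct = float(-(pos - lse).mean())
    w = np.exp(masked - lse[:, None])                  # negatives softmax, row-stoch
    onehot = np.zeros((S, n_way))
    onehot[np.arange(S), cs] = 1.0
    # dL_CT/d sims = (w - onehot)/S ; chain to embeddings and prototypes
    dsims_ct = (w - onehot) / S
    dHs = (dsims_ct @ protos) / tau
    dprotos = (dsims_ct.T @ Hs) / tau

    # --- classification term ---
    if len(cq) > 0:
        qs = Hq @ protos.T / tau
        P = softmax(qs, axis=1)
        picked = np.maximum(P[np.arange(len(cq)), cq], PROB_CLAMP)
        l_ce = float(-np.log(picked).mean())
        onehot_q = np.zeros_like(P)
        onehot_q[np.arange(len(cq)), cq] = 1.0
        dqs = (P - onehot_q) / len(cq)
        dHq = (dqs @ protos) / tau
        dprotos_ce = (dqs.T @ Hq) / tau
    else:
        l_ce = 0.0
        dHq = np.zeros_like(Hq)
        dprotos_ce = np.zeros_like(dprotos)

    l_t = combined_loss(l_ct, l_ce, alpha)
    dHs_total = alpha * dHs
    dHq_total = (1.0 - alpha) * dHq
    dprotos_total = alpha * dprotos + (1.0 - alpha) * dprotos_ce
    # prototypes are support means: dL/dh_s += dL/dproto_{c(s)} / m_{c(s)}
    dHs_total = dHs_total + dprotos_total[cs] / counts[cs, None]
    return LossBreakdown(l_ct, l_ce, l_t, protos), dHs_total, dHq_total


class _Adam:
    def __init__(self, size: int, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(size)
        self.v = np.zeros(size)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad ** 2
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return -self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    params: EncoderParams
    embeddings: np.ndarray            # C x d_h
    log: list[dict]                   # per-episode loss records
    pseudo: PseudoLabels


def _episode_step(
    episode: Episode,
    features: np.ndarray,
    cache,
    params: EncoderParams,
    tau: float,
    alpha: float,
) -> tuple[LossBreakdown, list[np.ndarray], list[np.ndarray]]:
    """Forward all episode spots through their subgraphs, compute L_T, and
    backpropagate to parameter gradients."""
    spots = np.concatenate([episode.support_nodes, episode.query_nodes])
    batch = batch_for_spots(spots, cache, features)
    emb = batch.forward(params, cache=True)
    n_s = len(episode.support_nodes)
    losses, dHs, dHq = episode_losses_and_grads(
        emb[:n_s], episode.support_classes,
        emb[n_s:], episode.query_classes,
        tau, alpha,
    )
    d_centers = np.vstack([dHs, dHq]) if len(dHq) else dHs
    dW, db = batch.backward(params, d_centers)
    return losses, dW, db


def train(
    dataset: SpotDataset,
    graph: SpotGraph,
    config: RunConfig,
    candidates: np.ndarray | None = None,
    pseudo: PseudoLabels | None = None,
    sequential_steps: bool = False,
) -> TrainResult:
    """Run episodic training and return the encoder, embeddings, and log.

    Pseudo-labels are computed once on the expression matrix before
    training (refresh per epoch via ``config.refresh_pseudo_labels``);
    episodes then sample support/query sets from the hard labels.  The
    run is deterministic per ``config.seed``.
    """
    X = dataset.expression
    rng = np.random.default_rng(config.seed)
    if pseudo is None:
        pseudo = fit_soft_kmeans(
            X, config.k_clusters, seed=config.seed,
            pca_components=config.pca_components,
        )
    if config.standardize_features:
        # per-gene z-scoring keeps encoder dot products at unit scale; the
        # contrastive objective has no finite minimum, so feature and
        # learning-rate scale control how long training stays in the
        # well-behaved regime
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-8)
    cache = build_subgraph_cache(graph, X)
    params = init_params(
        X.shape[1], config.hidden_dims, config.d_h, config.activation, rng
    )
    n_params = params.flat().size
    opt = _Adam(n_params, config.learning_rate)
    log: list[dict] = []
    for epoch in range(config.n_epochs):
        if config.refresh_pseudo_labels and epoch > 0:
            H = encode_all(X, graph, params, cache=cache)
            pseudo = fit_soft_kmeans(H, config.k_clusters, seed=config.seed)
        for ep_idx in range(config.episodes_per_epoch):
            episode = sample_episode(
                pseudo.hard_labels, config.n_way, config.m_shot,
                config.q_query, rng, candidates=candidates,
            )
            if sequential_steps:
                for a in (1.0, 0.0):
                    losses, dW, db = _episode_step(
                        episode, X, cache, params, config.tau, a
                    )
                    _apply(params, opt, dW, db,
                           scale=config.alpha if a == 1.0 else 1 - config.alpha)
            else:
                losses, dW, db = _episode_step(
                    episode, X, cache, params, config.tau, config.alpha
                )
                _apply(params, opt, dW, db)
            if not np.isfinite(losses.combined):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, episode {ep_idx}: "
                    f"L_T={losses.combined}"
                )
            log.append({
                "epoch": epoch, "episode": ep_idx,
                "loss_contrastive": losses.contrastive,
                "loss_classification": losses.classification,
                "loss_combined": losses.combined,
            })
    H = encode_all(X, graph, params, cache=cache)
    return TrainResult(params=params, embeddings=H, log=log, pseudo=pseudo)


def _apply(params: EncoderParams, opt: _Adam, dW, db, scale: float = 1.0) -> None:
    grad = np.concatenate([g.ravel() for g in dW + db]) * scale
    delta = opt.step(grad)
    vec = params.flat() + delta
    params.set_flat(vec)
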