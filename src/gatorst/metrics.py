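"""Clustering and imputation evaluation metrics, and the multi-seed harness.

Clustering agreement against ground-truth domains is scored with five
standard external metrics: ARI (pair-counting, chance-adjusted), NMI
(arithmetic-mean normalization), clustering accuracy ACC (optimal
one-to-one cluster-to-class alignment via the Hungarian algorithm on the
contingency table), purity (summed per-cluster majority counts / C), and
homogeneity (1 - H(class|cluster)/H(class), natural logs).  Imputation is
scored by Pearson correlation, mean absolute deviation (L1), and RMSE
over the evaluated (masked) entries.

The experiment harness repeats the whole pipeline over seeds: each run
re-splits the spots 80%/10%/10%, re-initializes the model, trains, and
evaluates; the mean over seeds is the dataset-level summary statistic.
A thin Wilcoxon signed-rank helper supports paired cross-method
comparison over dataset-level means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr, wilcoxon
from sklearn.metrics import (adjusted_rand_score, homogeneity_score,
                             normalized_mutual_info_score)
from sklearn.metrics.cluster import contingency_matrix

from .datasets import RunConfig, SpotDataset, split_spots
from .graph import build_knn_graph
from .meta import train
from .tasks import fit_imputation_head, identify_domains, impute_expression


@dataclass
class ClusteringScores:
    ari: float
    nmi: float
    acc: float
    purity: float
    homogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {"ari": self.ari, "nmi": self.nmi, "acc": self.acc,
                "purity": self.purity, "homogeneity": self.homogeneity}


@dataclass
class ImputationScores:
    pcc: float
    l1: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return {"pcc": self.pcc, "l1": self.l1, "rmse": self.rmse}


@dataclass
class MetricReport:
    """Per-seed metric values with mean and sd summaries."""

    per_seed: list[dict[str, float]]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        keys = self.per_seed[0].keys()
        self.mean = {k: float(np.mean([r[k] for r in self.per_seed])) for k in keys}
        self.sd = {k: float(np.std([r[k] for r in self.per_seed])) for k in keys}


def clustering_metrics(predicted: np.ndarray, truth: np.ndarray) -> ClusteringScores:
    """All five clustering metrics; invariant to relabeling of cluster ids."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    if len(predicted) < 2:
        raise ValueError("need at least 2 spots")
    cont = contingency_matrix(truth, predicted)
    n = cont.sum()
    # ACC: optimal one-to-one alignment (maximize matched counts)
    rows, cols = linear_sum_assignment(-cont)
    acc = cont[rows, cols].sum() / n
    purity = cont.max(axis=0).sum() / n
    return ClusteringScores(
        ari=float(adjusted_rand_score(truth, predicted)),
        nmi=float(normalized_mutual_info_score(truth, predicted,
                                               average_method="arithmetic")),
        acc=float(acc),
        purity=float(purity),
        homogeneity=float(homogeneity_score(truth, predicted)),
    )


def imputation_metrics(
    imputed: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> ImputationScores:
    """PCC / L1 / RMSE over the masked entries (all entries if no mask)."""
    imputed = np.asarray(imputed, float)
    truth = np.asarray(truth, float)
    if imputed.shape != truth.shape:
        raise ValueError("matrices must have equal shape")
    if mask is None:
        a, b = imputed.ravel(), truth.ravel()
    else:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty evaluation mask")
        a, b = imputed[mask], truth[mask]
    if np.std(b) == 0 or np.std(a) == 0:
        raise ValueError("zero variance in evaluated values; PCC undefined")
    resid = a - b
    return ImputationScores(
        pcc=float(pearsonr(a, b).statistic),
        l1=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid ** 2).mean())),
    )


def run_multi_seed(
    dataset: SpotDataset,
    config: RunConfig,
    seeds: list[int] | int = 10,
    n_domains: int | None = None,
    imputation_mask_rate: float = 0.0,
) -> MetricReport:
    """Repeat split / train / evaluate over seeds and summarize.

    Each seed re-splits the spots into train/validation/test (80/10/10 by
    default), re-initializes the encoder, samples episodes from the train
    split only, clusters the resulting embeddings into ``n_domains``
    (defaulting to the annotation count when truth labels exist), and
    scores against the truth.  With ``imputation_mask_rate`` > 0, a
    random entry mask is held out, the imputation head is fitted on the
    observed entries of the train split, and masked entries are scored.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    if dataset.true_labels is None and n_domains is None:
        raise ValueError("n_domains required when the dataset has no truth labels")
    k_domains = n_domains or len(np.unique(dataset.true_labels))
    graph = build_knn_graph(dataset.coordinates, config.k_neighbors,
                            similarity=config.similarity)
    rows = []
    for seed in seeds:
        cfg = RunConfig(**{**config.__dict__, "seed": seed})
        train_idx, val_idx, test_idx = split_spots(
            dataset.n_spots, cfg.split_fractions, seed=seed
        )
        result = train(dataset, graph, cfg, candidates=train_idx)
        domains = identify_domains(result.embeddings, k_domains, seed=seed)
        row: dict[str, float] = {"seed": float(seed)}
        if dataset.true_labels is not None:
            row.update(clustering_metrics(domains.assignments,
                                          dataset.true_labels).as_dict())
        if imputation_mask_rate > 0:
            rng = np.random.default_rng(seed)
            mask = rng.random(dataset.expression.shape) < imputation_mask_rate
            head = fit_imputation_head(result.embeddings, dataset.expression,
                                       mask=mask)
            imputed = impute_expression(result.embeddings, head)
            row.update(imputation_metrics(imputed, dataset.expression,
                                          mask=mask).as_dict())
        rows.append(row)
    return MetricReport(per_seed=rows)


def paired_wilcoxon(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value over paired dataset-level
    mean scores of two methods (no normality assumption)."""
    return float(wilcoxon(scores_a, scores_b, alternative="two-sided").pvalue)
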