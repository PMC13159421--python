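"""Spot-level dataset container, on-disk formats, and split utilities.

A spatial transcriptomics dataset is a spot-by-gene expression matrix
``X`` (C spots x g genes) paired with a spot-by-coordinate table (2-D or
3-D spatial locations), plus optional per-spot batch identifiers and
ground-truth domain labels used only for evaluation.

Supported on-disk formats: dense CSV/TSV (spots x genes, header row of
gene names, first column spot ids) and MatrixMarket (MTX) triplets with
companion row/column name files.  Coordinates and label vectors are plain
CSV with a header.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix


class AlignmentError(ValueError):
    """Row counts of expression and coordinate tables disagree."""


@dataclass
class SpotDataset:
    """Expression + spatial coordinates for C spots, g genes.

    Attributes
    ----------
    expression : (C, g) float array, nonnegative
    coordinates : (C, z) float array, z typically 2
    spot_ids : list of C unique identifiers
    gene_names : list of g gene names
    batch_ids : optional (C,) array of batch labels
    true_labels : optional (C,) array of ground-truth domain labels
    """

    expression: np.ndarray
    coordinates: np.ndarray
    spot_ids: list[str]
    gene_names: list[str]
    batch_ids: np.ndarray | None = None
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.expression.shape[0] != self.coordinates.shape[0]:
            raise AlignmentError(
                f"expression has {self.expression.shape[0]} rows but "
                f"coordinates has {self.coordinates.shape[0]}"
            )
        if len(self.spot_ids) != self.expression.shape[0]:
            raise AlignmentError("spot_ids length does not match expression rows")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicate spot_ids")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class RunConfig:
    """Hyperparameters of a full training + evaluation run.

    ``tau`` is the contrastive temperature; ``alpha`` in [0,1] balances
    the contrastive loss against the episode classification loss.  An
    episode is an N-way, M-shot task with up to ``q_query`` query spots.
    """

    k_neighbors: int = 6
    k_clusters: int = 10           # pseudo-label clusters K
    d_h: int = 64
    hidden_dims: tuple[int, ...] = (128,)
    tau: float = 0.5
    alpha: float = 0.5
    n_way: int = 5
    m_shot: int = 5
    q_query: int = 15
    episodes_per_epoch: int = 50
    n_epochs: int = 40
    learning_rate: float = 1e-5
    batch_size: int = 32
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    activation: str = "relu"
    pca_components: int | None = 50  # pseudo-label input reduction; None = raw X
    standardize_features: bool = True  # z-score genes before the encoder
    refresh_pseudo_labels: bool = False
    similarity: str = "proximity"  # or "inner-product"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.n_way > self.k_clusters:
            raise ValueError("n_way cannot exceed k_clusters")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        for name in ("k_neighbors", "k_clusters", "d_h", "n_way", "m_shot",
                     "q_query", "episodes_per_epoch", "n_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("hidden_dims", "split_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_expression(path: str | Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Return (matrix, gene_names, spot_ids or None)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = np.asarray(mmread(str(path)).todense(), dtype=float)
        rows_file = path.with_name(path.stem + "_rows.txt")
        cols_file = path.with_name(path.stem + "_cols.txt")
        spot_ids = rows_file.read_text().split() if rows_file.exists() else None
        if cols_file.exists():
            genes = cols_file.read_text().split()
        else:
            genes = [f"gene{j}" for j in range(mat.shape[1])]
        return mat, genes, spot_ids
    df = _read_table(path)

    def _not_numeric(v) -> bool:
        try:
            float(v)
            return False
        except (TypeError, ValueError):
            return True

    bad = df.map(_not_numeric).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric expression value at row {i} ({df.index[i]}), "
            f"column {j} ({df.columns[j]})"
        )
    df = df.astype(float)
    genes = _dedupe_names([str(c) for c in df.columns])
    return df.to_numpy(dtype=float), genes, [str(i) for i in df.index]


def _dedupe_names(names: list[str]) -> list[str]:
    # duplicated gene symbols keep all columns; suffix later copies
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_dataset(
    expression_path: str | Path,
    coordinates_path: str | Path,
    labels_path: str | Path | None = None,
    batches_path: str | Path | None = None,
) -> SpotDataset:
    """Read a spot dataset from disk.

    Spots follow the order of the coordinates file; genes the order of the
    expression header.  No gene filtering is applied: all-zero genes are
    kept.
    """
    coords_df = _read_table(coordinates_path)
    X, genes, expr_ids = _read_expression(expression_path)
    spot_ids = [str(i) for i in coords_df.index]
    if X.shape[0] != len(spot_ids):
        raise AlignmentError(
            f"expression has {X.shape[0]} rows but coordinates has {len(spot_ids)}"
        )
    if expr_ids is not None and expr_ids != spot_ids:
        if sorted(expr_ids) == sorted(spot_ids):
            order = [expr_ids.index(s) for s in spot_ids]
            X = X[order]
        else:
            raise AlignmentError("expression and coordinate spot ids disagree")
    labels = batches = None
    if labels_path is not None:
        labels = _read_table(labels_path).iloc[:, 0].to_numpy()
        if len(labels) != len(spot_ids):
            raise AlignmentError("label vector length does not match spot count")
    if batches_path is not None:
        batches = _read_table(batches_path).iloc[:, 0].to_numpy()
        if len(batches) != len(spot_ids):
            raise AlignmentError("batch vector length does not match spot count")
    return SpotDataset(
        expression=X,
        coordinates=coords_df.to_numpy(dtype=float),
        spot_ids=spot_ids,
        gene_names=genes,
        batch_ids=batches,
        true_labels=labels,
    )


def write_dataset(dataset: SpotDataset, out_dir: str | Path, sparse: bool = False) -> dict[str, str]:
    """Write a dataset in the formats :func:`read_dataset` accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if sparse:
        path = out / "expression.mtx"
        mmwrite(str(path), csr_matrix(dataset.expression))
        (out / "expression_rows.txt").write_text("\n".join(dataset.spot_ids) + "\n")
        (out / "expression_cols.txt").write_text("\n".join(dataset.gene_names) + "\n")
        manifest["expression"] = str(path)
    else:
        path = out / "expression.csv"
        pd.DataFrame(dataset.expression, index=dataset.spot_ids,
                     columns=dataset.gene_names).to_csv(path)
        manifest["expression"] = str(path)
    cpath = out / "coordinates.csv"
    cols = [f"dim{i}" for i in range(dataset.coordinates.shape[1])]
    pd.DataFrame(dataset.coordinates, index=dataset.spot_ids, columns=cols).to_csv(cpath)
    manifest["coordinates"] = str(cpath)
    if dataset.true_labels is not None:
        lpath = out / "labels.csv"
        pd.DataFrame({"domain": dataset.true_labels}, index=dataset.spot_ids).to_csv(lpath)
        manifest["labels"] = str(lpath)
    if dataset.batch_ids is not None:
        bpath = out / "batches.csv"
        pd.DataFrame({"batch": dataset.batch_ids}, index=dataset.spot_ids).to_csv(bpath)
        manifest["batches"] = str(bpath)
    return manifest


def write_outputs(
    out_dir: str | Path,
    spot_ids: list[str],
    labels: np.ndarray | None = None,
    embeddings: np.ndarray | None = None,
    imputed: np.ndarray | None = None,
    gene_names: list[str] | None = None,
) -> dict[str, str]:
    """Write run outputs (domain labels, embeddings, imputed expression).

    Returns a manifest mapping output kind to the written path.
    """
    if labels is None and embeddings is None and imputed is None:
        raise ValueError("nothing to write")
    C = len(spot_ids)
    for name, arr in (("labels", labels), ("embeddings", embeddings), ("imputed", imputed)):
        if arr is not None and len(arr) != C:
            raise ValueError(f"{name} has {len(arr)} rows, expected {C}")
        if arr is not None and len(arr) == 0:
            raise ValueError(f"{name} is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise OSError(f"output directory not writable: {out}")
    manifest: dict[str, str] = {}
    if labels is not None:
        p = out / "domains.csv"
        pd.DataFrame({"spot_id": spot_ids, "domain": labels}).to_csv(p, index=False)
        manifest["labels"] = str(p)
    if embeddings is not None:
        p = out / "embeddings.csv"
        cols = [f"h{i}" for i in range(embeddings.shape[1])]
        pd.DataFrame(embeddings, index=spot_ids, columns=cols).to_csv(p)
        manifest["embeddings"] = str(p)
    if imputed is not None:
        p = out / "imputed.csv"
        cols = gene_names or [f"gene{i}" for i in range(imputed.shape[1])]
        pd.DataFrame(imputed, index=spot_ids, columns=cols).to_csv(p)
        manifest["imputed"] = str(p)
    return manifest


def split_spots(
    n_spots: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomly partition ``range(n_spots)`` into train/val/test index sets.

    Set sizes follow largest-remainder rounding of the fractions, so they
    are exact for e.g. (0.8, 0.1, 0.1) with n divisible by 10.  The split
    is deterministic per seed.
    """
    if n_spots < 3:
        raise ValueError("need at least 3 spots to split")
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    ideal = fr * n_spots
    sizes = np.floor(ideal).astype(int)
    rem = ideal - sizes
    for i in np.argsort(-rem)[: n_spots - sizes.sum()]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_spots)
    train = np.sort(perm[: sizes[0]])
    val = np.sort(perm[sizes[0]: sizes[0] + sizes[1]])
    test = np.sort(perm[sizes[0] + sizes[1]:])
    return train, val, test
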