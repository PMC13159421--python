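"""Spot-spot k-NN graph over spatial coordinates and two-hop subgraphs.

The graph is purely spatial: each spot selects its ``k`` most similar
spots (by default, similarity = negative Euclidean distance between the
location vectors, i.e. spatial proximity) and the adjacency is the union
symmetrization of those selections, binary, with zero diagonal.  A raw
inner-product similarity over the coordinate vectors is available behind
``similarity="inner-product"`` for comparison experiments, but it is not
a proximity measure (it favors spots far from the coordinate origin) and
is not the default.

Each spot's receptive field for the encoder is its two-hop subgraph: the
induced subgraph on all nodes at shortest-path distance <= 2 from the
center.  Three-hop neighborhoods are deliberately unsupported — they add
cost without improving the learned representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix


@dataclass
class SpotGraph:
    """Binary symmetric k-NN adjacency over C spots (zero diagonal)."""

    adjacency: csr_matrix
    k: int

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[v]: self.adjacency.indptr[v + 1]
        ]


@dataclass
class Subgraph:
    """Induced two-hop neighborhood of a center spot.

    ``nodes`` lists original spot ids with the center first; ``adjacency``
    and ``features`` are restricted to and ordered by ``nodes``;
    ``hop_distance[i]`` is the BFS distance from the center to
    ``nodes[i]`` (0, 1, or 2).
    """

    center: int
    nodes: np.ndarray
    adjacency: np.ndarray        # dense |V_v| x |V_v|, small by construction
    features: np.ndarray
    hop_distance: np.ndarray


def build_knn_graph(
    coordinates: np.ndarray, k: int, similarity: str = "proximity"
) -> SpotGraph:
    """Build the spot-spot graph: each node links to its k most similar nodes.

    Ties at equal similarity are broken toward the lower node index, so
    the construction is deterministic on lattice data where ties abound.
    The edge set is the union over both endpoints' selections.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coordinates must be a C x z matrix with C >= 1")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    if k < 1:
        raise ValueError("k must be >= 1")
    C = coords.shape[0]
    if C == 1:
        return SpotGraph(adjacency=csr_matrix((1, 1)), k=k)
    if similarity == "proximity":
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        score = -d2
    elif similarity == "inner-product":
        score = coords @ coords.T
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    np.fill_diagonal(score, -np.inf)
    kk = min(k, C - 1)
    # stable sort on (-score, index): ties go to the lower index
    order = np.argsort(-score, axis=1, kind="stable")
    sel = order[:, :kk]
    rows = np.repeat(np.arange(C), kk)
    cols = sel.ravel()
    A = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(C, C)).tocsr()
    A = ((A + A.T) > 0).astype(np.int8).tocsr()  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    return SpotGraph(adjacency=A, k=k)


def two_hop_nodes(graph: SpotGraph, v: int) -> tuple[np.ndarray, np.ndarray]:
    """BFS to depth 2: returns (nodes, hop distances), center first."""
    C = graph.node_count
    if not (0 <= v < C):
        raise IndexError(f"node {v} out of range [0, {C})")
    one = graph.neighbors(v)
    two = np.unique(graph.adjacency[one].indices) if one.size else np.array([], dtype=int)
    dist = np.full(C, -1, dtype=int)
    dist[v] = 0
    dist[one] = 1
    fresh = two[dist[two] == -1]
    dist[fresh] = 2
    nodes = np.concatenate([[v], np.sort(one), np.sort(fresh)]).astype(int)
    return nodes, dist[nodes]


def extract_two_hop_subgraph(
    graph: SpotGraph, features: np.ndarray, v: int
) -> Subgraph:
    """Induced subgraph on the center plus its one- and two-hop neighbors."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] != graph.node_count:
        raise ValueError("feature rows must match graph node count")
    nodes, hops = two_hop_nodes(graph, v)
    sub = graph.adjacency[np.ix_(nodes, nodes)].toarray().astype(float)
    return Subgraph(
        center=v,
        nodes=nodes,
        adjacency=sub,
        features=features[nodes],
        hop_distance=hops,
    )


def edge_list(graph: SpotGraph) -> np.ndarray:
    """Upper-triangular edge list (i, j) with i < j, for export/debugging."""
    coo = graph.adjacency.tocoo()
    mask = coo.row < coo.col
    return np.column_stack([coo.row[mask], coo.col[mask]])
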