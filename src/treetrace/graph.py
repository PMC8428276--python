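"""kNN graph construction and community-detection clustering in PC space."""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors


@dataclass
class CellGraph:
    """Undirected weighted kNN graph over cells in selected-PC space.

    The directed k-nearest-neighbor relation is symmetrized by union, so a
    rare cell pulled in as someone's neighbor stays connected even when its
    own neighbors are elsewhere.  Edge weights are Euclidean distances.
    ``coords`` retains the embedding the graph was built from (used later
    for centroids and for bridging disconnected components).
    """

    adjacency: sp.csr_matrix  # symmetric, weight = distance, no self-loops
    k_used: int
    coords: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        """Unordered edge list (i < j, weight)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return [(int(i), int(j), float(w))
                for i, j, w in zip(coo.row, coo.col, coo.data)]

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()


@dataclass
class Clustering:
    """Cell-to-cluster assignment with per-cluster centroids.

    Cluster IDs are integers starting at 1, relabeled by decreasing size so
    reports are stable across runs.  Centroids are means of member
    coordinates in the same PC space used to build the graph.
    """

    labels: np.ndarray  # int, 1..C
    centroids: dict[int, np.ndarray]
    algorithm: str
    k_used: int
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.centroids)

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        idx = cell_ids if cell_ids is not None else np.arange(len(self.labels))
        return pd.DataFrame({"cell_id": idx, "cluster": self.labels})


def build_knn_graph(coords: np.ndarray, k: int) -> CellGraph:
    """Union-symmetrized kNN graph with Euclidean edge weights.

    Distance ties are broken by lower cell index, making the graph
    deterministic for any input.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=min(k + 2, n), algorithm="auto")
    nn.fit(coords)
    dist, idx = nn.kneighbors(coords)
    rows, cols, vals = [], [], []
    for i in range(n):
        # drop self, re-sort by (distance, index) for deterministic ties
        cand = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i]
        cand.sort()
        for d, j in cand[:k]:
            rows.append(i)
            cols.append(j)
            vals.append(d)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # union symmetrization
    return CellGraph(adjacency=A, k_used=k, coords=coords)


def bridge_components(graph: CellGraph) -> CellGraph:
    """Connect disconnected components with shortest Euclidean edges.

    Geodesic computations and cluster-level shortest paths need finite
    distances everywhere; each round adds the single shortest
    inter-component edge (in the PC space the graph was built from)
    until one component remains.  A connected graph is returned as-is.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import cdist

    n_comp, _ = connected_components(graph.adjacency, directed=False)
    if n_comp == 1:
        return graph
    A = graph.adjacency.tolil(copy=True)
    while True:
        n_comp, labels = connected_components(A.tocsr(), directed=False)
        if n_comp == 1:
            return CellGraph(adjacency=A.tocsr(), k_used=graph.k_used,
                             coords=graph.coords)
        best = None
        comp_idx = [np.nonzero(labels == c)[0] for c in range(n_comp)]
        for a in range(n_comp):
            for b in range(a + 1, n_comp):
                D = cdist(graph.coords[comp_idx[a]], graph.coords[comp_idx[b]])
                i, j = np.unravel_index(np.argmin(D), D.shape)
                if best is None or D[i, j] < best[0]:
                    best = (D[i, j], int(comp_idx[a][i]), int(comp_idx[b][j]))
        d, i, j = best
        A[i, j] = d
        A[j, i] = d


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Relabel community ids to 1..C by decreasing size (ties: old id)."""
    ids, counts = np.unique(membership, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[m] for m in membership], dtype=int)


def cluster_communities(
    graph: CellGraph,
    algorithm: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
) -> Clustering:
    """Community detection (Leiden or Louvain) on the unweighted topology.

    Modularity-style partitioning runs on the graph's topology only; edge
    distances are not used as weights.  Reproducible for a fixed seed.
    """
    edges = [(i, j) for i, j, _ in graph.edges]
    g = ig.Graph(n=graph.n_cells, edges=edges, directed=False)
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    elif algorithm == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel()
        membership = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    labels = _relabel_by_size(membership)
    centroids = {int(c): graph.coords[labels == c].mean(axis=0)
                 for c in np.unique(labels)}
    return Clustering(labels=labels, centroids=centroids,
                      algorithm=algorithm, k_used=graph.k_used, seed=seed)


def sweep_k(
    coords: np.ndarray,
    k_values=range(4, 21),
    algorithm: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
) -> list[tuple[int, Clustering, int]]:
    """Cluster once per k in ``k_values`` (default 4..20) and tabulate.

    Smaller k fragments the graph more and tends to produce more, smaller
    clusters — useful for isolating rare populations.  The caller inspects
    the summary and picks the clustering appropriate to the question.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values is empty")
    out = []
    for k in k_values:
        graph = build_knn_graph(coords, k)
        clus = cluster_communities(graph, algorithm=algorithm,
                                   resolution=resolution, seed=seed)
        out.append((k, clus, clus.n_clusters))
    return out


def sweep_summary(sweep: list[tuple[int, Clustering, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(k, n) for k, _, n in sweep], columns=["k", "n_clusters"]
    )
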