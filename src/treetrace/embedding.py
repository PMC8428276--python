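"""3-D landmark ISOMAP with per-cluster graph hubs as landmarks.

Geodesic distances are computed landmark-first: one single-source
shortest-path search per landmark instead of an all-pairs solve, which is
what makes the embedding cheap on large graphs.  Classical metric MDS on
the landmark-landmark block plus distance-based triangulation places the
remaining cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .graph import CellGraph, Clustering, bridge_components


@dataclass
class LandmarkSet:
    """Graph hubs chosen per cluster to anchor the embedding.

    A hub is the cluster member with the most kNN-graph connections to
    other members of the same cluster; well-connected cells sit centrally
    and give stable geodesics.
    """

    landmark_cells: list[int]
    source_cluster: dict[int, int]  # landmark cell -> cluster id
    hub_degree: dict[int, int]  # landmark cell -> intra-cluster degree

    def __len__(self) -> int:
        return len(self.landmark_cells)


@dataclass
class Embedding3D:
    """Cell coordinates in the embedded space (typically 3-D).

    ``stress`` is the relative residual between geodesic and embedded
    distances over landmark pairs (0 = perfect metric reproduction).
    """

    coords: np.ndarray  # cells x dim
    stress: float
    landmark_coords: np.ndarray  # landmarks x dim
    landmark_cells: list[int]


def find_hubs(graph: CellGraph, clustering: Clustering,
              hubs_per_cluster: int = 1, min_landmarks: int | None = None) -> LandmarkSet:
    """Pick the best-connected members of each cluster as landmarks.

    Per cluster the ``hubs_per_cluster`` members with the highest
    intra-cluster degree are taken, ties broken by lower cell index.  If
    the total falls below ``min_landmarks`` (default max(10, n_clusters, 5)),
    ``hubs_per_cluster`` is raised automatically so the later triangulation
    stays well-posed.
    """
    if hubs_per_cluster < 1:
        raise ValueError("hubs_per_cluster must be >= 1")
    if min_landmarks is None:
        min_landmarks = max(10, clustering.n_clusters, 5)

    A = (graph.adjacency > 0).astype(int)

    def pick(per_cluster: int) -> LandmarkSet:
        cells: list[int] = []
        source: dict[int, int] = {}
        degree: dict[int, int] = {}
        for c in clustering.cluster_ids:
            members = clustering.members(c)
            if len(members) == 1:
                warnings.warn(f"cluster {c} is a singleton; using its only cell as hub")
                deg_in = np.array([0])
            else:
                sub = A[np.ix_(members, members)]
                deg_in = np.asarray(sub.sum(axis=1)).ravel()
            # ties by lower cell index: lexsort on (-degree, member index)
            order = np.lexsort((members, -deg_in))
            take = min(per_cluster, len(members))
            for o in order[:take]:
                cell = int(members[o])
                cells.append(cell)
                source[cell] = c
                degree[cell] = int(deg_in[o])
        return LandmarkSet(sorted(cells), source, degree)

    per = hubs_per_cluster
    lm = pick(per)
    while len(lm) < min_landmarks and per < graph.n_cells:
        per += 1
        new = pick(per)
        if len(new) == len(lm):  # saturated: every cell already a landmark
            break
        lm = new
    return lm


def geodesics_from_landmarks(graph: CellGraph,
                             landmarks: LandmarkSet) -> np.ndarray:
    """Weighted shortest-path distances, landmarks x all cells.

    Runs one Dijkstra search per landmark on the (bridged) kNN graph.
    The searches are independent; running them in any order or in
    parallel yields identical results.
    """
    A = bridge_components(graph).adjacency
    D = dijkstra(A, directed=False, indices=landmarks.landmark_cells)
    return np.asarray(D)


def landmark_mds_embed(D: np.ndarray, landmark_cells: list[int],
                       dim: int = 3) -> Embedding3D:
    """Classical landmark MDS of a landmark x cell geodesic matrix.

    The landmark-landmark squared-distance block is double-centered and
    eigendecomposed; the top-``dim`` eigenpairs give landmark coordinates.
    Every other cell is placed by the standard triangulation formula:
    x_i = -1/2 * L# (delta_i - delta_mean) with L# the pseudo-inverse
    transposed coordinate matrix and delta the squared distances to
    landmarks.  Negative eigenvalues (non-Euclidean geodesics) are
    truncated at zero; axes are eigenvalue-ordered and sign-fixed.
    """
    D = np.asarray(D, dtype=float)
    n_land, n_cells = D.shape
    if n_land < dim + 2:
        raise ValueError(f"need at least {dim + 2} landmarks, got {n_land}")

    Dll2 = D[:, landmark_cells] ** 2
    J = np.eye(n_land) - np.ones((n_land, n_land)) / n_land
    B = -0.5 * J @ Dll2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_pos = int(np.sum(evals[:dim] > 1e-12))
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dim - n_pos} zero axes"
        )
    lam = np.clip(evals[:dim], 0.0, None)
    V = evecs[:, :dim]
    L = V * np.sqrt(lam)  # landmark coordinates, n_land x dim

    # triangulation of all cells from their squared distances to landmarks
    with np.errstate(divide="ignore", invalid="ignore"):
        Lsharp = np.where(lam > 1e-12, V / np.sqrt(np.where(lam > 0, lam, 1.0)), 0.0).T
    delta_mean = Dll2.mean(axis=1)
    X = -0.5 * (Lsharp @ (D ** 2 - delta_mean[:, None]))
    coords = X.T  # cells x dim

    # sign convention: largest-|coordinate| landmark positive on each axis
    for j in range(dim):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] *= -1
            coords[:, j] *= -1
    coords[landmark_cells] = L  # enforce exact landmark placement

    emb_d = cdist(L, L)
    geo_d = D[:, landmark_cells]
    denom = np.sum(geo_d ** 2)
    stress = float(np.sqrt(np.sum((emb_d - geo_d) ** 2) / denom)) if denom > 0 else 0.0
    return Embedding3D(coords=coords, stress=stress, landmark_coords=L,
                       landmark_cells=list(landmark_cells))


def lisomap(graph: CellGraph, clustering: Clustering,
            hubs_per_cluster: int = 1, dim: int = 3) -> Embedding3D:
    """Full pipeline: hubs -> landmark geodesics -> landmark MDS."""
    lm = find_hubs(graph, clustering, hubs_per_cluster,
                   min_landmarks=max(10, clustering.n_clusters, dim + 2))
    D = geodesics_from_landmarks(graph, lm)
    return landmark_mds_embed(D, lm.landmark_cells, dim=dim)
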