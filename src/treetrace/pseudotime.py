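"""Cell-level pseudotime from the cluster trajectory tree.

Each cell is placed on a tree edge incident to its own cluster: the cell
is orthogonally projected onto the segment joining the two endpoint
cluster centroids in PC space, and among the candidate edges the one with
the smallest perpendicular residual wins.  Pseudotime is the cumulative
edge length from the root up to the projected position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Clustering
from .tree import TrajectoryTree


@dataclass
class PseudotimeAssignment:
    """Per-cell edge placement and pseudotime.

    ``offset`` is the fractional position along the (parent -> child)
    edge, clamped to [0, 1]; pseudotime = depth(parent) + offset * length.
    ``branch`` labels the cell by the smallest-id leaf whose root path
    contains its edge (shared trunk edges thus carry one stable label).
    """

    edge: list[tuple[int, int]]
    offset: np.ndarray
    pseudotime: np.ndarray
    branch: list[int]

    def to_frame(self, cell_ids=None, normalized: bool = True) -> pd.DataFrame:
        n = len(self.offset)
        idx = cell_ids if cell_ids is not None else np.arange(n)
        df = pd.DataFrame({
            "cell_id": idx,
            "pseudotime": self.pseudotime,
            "branch": self.branch,
            "edge_parent": [e[0] for e in self.edge],
            "edge_child": [e[1] for e in self.edge],
            "offset": self.offset,
        })
        if normalized:
            span = self.pseudotime.max()
            df["pseudotime_norm"] = self.pseudotime / span if span > 0 else 0.0
        return df


def _edge_leaf_labels(tree: TrajectoryTree) -> dict[tuple[int, int], int]:
    """Label each oriented edge by the smallest leaf id reachable below it."""
    labels: dict[tuple[int, int], int] = {}
    for leaf in sorted(tree.leaves(), reverse=True):
        path = tree.path_to(leaf)
        for a, b in zip(path, path[1:]):
            labels[(a, b)] = leaf  # later (smaller) leaves overwrite
    return labels


def map_cells(tree: TrajectoryTree, clustering: Clustering,
              coords: np.ndarray) -> PseudotimeAssignment:
    """Project every cell onto a tree edge incident to its cluster.

    Cells of clusters merged into an on-tree host (``tree.merged``) are
    treated as members of the host cluster.
    """
    coords = np.asarray(coords, dtype=float)
    if tree.merged:
        clustering = Clustering(
            labels=np.array([tree.merged.get(int(c), int(c))
                             for c in clustering.labels]),
            centroids={c: v for c, v in clustering.centroids.items()
                       if c not in tree.merged},
            algorithm=clustering.algorithm,
            k_used=clustering.k_used,
            seed=clustering.seed,
        )
    node_set = set(tree.nodes)
    for cl in np.unique(clustering.labels):
        if int(cl) not in node_set:
            raise ValueError(f"cluster {int(cl)} is not a tree node")
    for n in tree.nodes:
        if n not in clustering.centroids:
            raise ValueError(f"tree node {n} has no cluster centroid")
    depths = {n: tree.depth(n) for n in tree.nodes}
    branch_of = _edge_leaf_labels(tree)

    # candidate (parent, child) edges per cluster
    incident: dict[int, list[tuple[int, int, float]]] = {n: [] for n in tree.nodes}
    for p, c, w in tree.edges:
        incident[p].append((p, c, w))
        incident[c].append((p, c, w))

    edges: list[tuple[int, int]] = []
    offsets = np.zeros(coords.shape[0])
    ptimes = np.zeros(coords.shape[0])
    branches: list[int] = []
    cent = clustering.centroids

    for i in range(coords.shape[0]):
        cl = int(clustering.labels[i])
        cands = incident[cl]
        if not cands:  # single-node tree
            edges.append((cl, cl))
            branches.append(cl)
            continue
        best = None
        for p, c, w in sorted(cands):
            a, b = cent[p], cent[c]
            seg = b - a
            denom = float(seg @ seg)
            t = float((coords[i] - a) @ seg) / denom if denom > 0 else 0.0
            t = min(1.0, max(0.0, t))
            resid = float(np.linalg.norm(coords[i] - (a + t * seg)))
            if best is None or resid < best[0] - 1e-12:
                best = (resid, p, c, t, w)
        _, p, c, t, w = best
        edges.append((p, c))
        offsets[i] = t
        ptimes[i] = depths[p] + t * w
        branches.append(branch_of.get((p, c), c))

    return PseudotimeAssignment(edge=edges, offset=offsets,
                                pseudotime=ptimes, branch=branches)


def branch_cells(assign: PseudotimeAssignment, tree: TrajectoryTree,
                 leaf: int) -> list[int]:
    """Cells on the root -> ``leaf`` path, ordered by ascending pseudotime.

    Ties in pseudotime break by cell index.
    """
    if not tree.leaf_flags.get(leaf, False) and leaf not in tree.leaves():
        raise ValueError(f"{leaf} is not a leaf of the tree")
    path = tree.path_to(leaf)
    path_edges = set(zip(path, path[1:]))
    members = [i for i, e in enumerate(assign.edge) if e in path_edges]
    return sorted(members, key=lambda i: (assign.pseudotime[i], i))
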