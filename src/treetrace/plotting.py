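"""Static figure exports: pie tree, cell-cluster tree, pseudotime map,
3-D embedding scatter, and per-branch trend heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .graph import Clustering
from .pseudotime import PseudotimeAssignment
from .tree import TrajectoryTree
from .trends import TrendResult, rank_genes


def _tree_layout(tree: TrajectoryTree) -> dict[int, tuple[float, float]]:
    """Simple layered layout: x spreads leaves, y is depth from root."""
    pos: dict[int, tuple[float, float]] = {}
    leaves = tree.leaves() or [tree.root]
    xs = {leaf: i for i, leaf in enumerate(sorted(leaves))}

    def place(node: int, depth: float) -> float:
        kids = sorted(tree.children(node))
        if not kids:
            x = xs.get(node, len(xs))
            pos[node] = (x, -depth)
            return x
        child_x = [place(c, depth + tree.edge_length(node, c)) for c in kids]
        x = float(np.mean(child_x))
        pos[node] = (x, -depth)
        return x

    place(tree.root, 0.0)
    return pos


def plot_pie_tree(tree: TrajectoryTree, clustering: Clustering,
                  annotation: dict[int, str] | None, path: str | Path) -> None:
    """Tree with one pie per cluster node showing composition by annotation.

    ``annotation`` maps cell index -> category; with ``None`` each node is
    a plain dot sized by cluster population.
    """
    pos = _tree_layout(tree)
    fig, ax = plt.subplots(figsize=(8, 6))
    for p, c, _ in tree.edges:
        ax.plot(*zip(pos[p], pos[c]), color="0.6", zorder=1)
    cats = sorted(set(annotation.values())) if annotation else []
    cmap = plt.get_cmap("tab20")
    for node, (x, y) in pos.items():
        members = clustering.members(node)
        if annotation and len(members):
            counts = np.array([
                sum(annotation.get(int(m), "") == cat for m in members)
                for cat in cats], dtype=float)
            if counts.sum() > 0:
                ax.pie(counts, center=(x, y), radius=0.25,
                       colors=[cmap(i % 20) for i in range(len(cats))],
                       frame=True)
        else:
            ax.scatter([x], [y], s=20 + 2 * len(members), color="steelblue",
                       zorder=2)
        ax.annotate(str(node), (x, y), textcoords="offset points",
                    xytext=(6, 6), fontsize=8)
    ax.set_axis_off()
    ax.set_title("trajectory pie tree")
    if cats:
        ax.legend(cats, fontsize=6, loc="upper right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_cluster_tree(tree: TrajectoryTree, clustering: Clustering,
                      assign: PseudotimeAssignment, path: str | Path,
                      seed: int = 0) -> None:
    """One box per cluster along the tree, cells jittered inside."""
    pos = _tree_layout(tree)
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(8, 6))
    for p, c, _ in tree.edges:
        ax.plot(*zip(pos[p], pos[c]), color="0.6", zorder=1)
    cmap = plt.get_cmap("tab20")
    for node, (x, y) in pos.items():
        members = clustering.members(node)
        jit = rng.normal(0, 0.06, size=(len(members), 2))
        ax.scatter(x + jit[:, 0], y + jit[:, 1], s=3,
                   color=cmap(node % 20), zorder=2)
        ax.annotate(str(node), (x, y), textcoords="offset points",
                    xytext=(8, 8), fontsize=8)
    ax.set_axis_off()
    ax.set_title("cell cluster tree")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_embedding3d(coords: np.ndarray, clustering: Clustering,
                     tree: TrajectoryTree | None, path: str | Path) -> None:
    """3-D scatter colored by cluster, optionally with the tree overlay."""
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    cmap = plt.get_cmap("tab20")
    for c in clustering.cluster_ids:
        m = clustering.members(c)
        ax.scatter(coords[m, 0], coords[m, 1], coords[m, 2], s=3,
                   color=cmap(c % 20), label=str(c))
    if tree is not None:
        centers = {c: coords[clustering.members(c)].mean(axis=0)
                   for c in clustering.cluster_ids if c in tree.nodes}
        for p, c, _ in tree.edges:
            if p in centers and c in centers:
                seg = np.stack([centers[p], centers[c]])
                ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], color="k", lw=1.5)
    ax.legend(fontsize=6, loc="upper right", ncol=2)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_pseudotime(coords2d: np.ndarray, pseudotime: np.ndarray,
                    path: str | Path) -> None:
    """2-D scatter colored by pseudotime."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords2d[:, 0], coords2d[:, 1], c=pseudotime, s=4,
                    cmap="viridis")
    fig.colorbar(sc, label="pseudotime")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_trend_heatmap(branch_values: np.ndarray, gene_ids: list[str],
                       result: TrendResult, rank: int, path: str | Path,
                       max_genes: int = 50) -> None:
    """Heatmap of the branch matrix with rows ordered by one rank's scores."""
    ordered = rank_genes(result, rank)
    if not ordered:
        return
    ordered = ordered[:max_genes // 2] + ordered[-max_genes // 2:] \
        if len(ordered) > max_genes else ordered
    idx = [result.gene_ids.index(g) for g, _ in ordered]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.12 * len(idx))))
    im = ax.imshow(branch_values[idx], aspect="auto", cmap="RdBu_r",
                   interpolation="nearest")
    ax.set_yticks(range(len(idx)))
    ax.set_yticklabels([g for g, _ in ordered], fontsize=5)
    ax.set_xlabel("pseudotime bin")
    ax.set_title(f"rank {rank} trend (genes ordered by score)")
    fig.colorbar(im)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
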