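"""End-to-end pipeline: preprocess -> PCA -> cluster -> embed -> tree ->
pseudotime -> per-branch trend analysis, with staged on-disk artifacts.

Each stage reads the previous stage's artifacts, so the monolithic
:func:`run_pipeline` and the CLI subcommands produce identical results
for identical configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import matrix as mx
from .config import RunConfig
from .embedding import lisomap
from .graph import (Clustering, bridge_components, build_knn_graph,
                    cluster_communities)
from .pseudotime import branch_cells, map_cells
from .simulate import SimDataset, preset
from .tree import LeafGroup, TrajectoryTree, cluster_distances, spanning_tree
from .trends import bin_branch, pta

log = logging.getLogger("treetrace")


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        # %.17g round-trips float64 exactly, keeping staged runs
        # artifact-equivalent to the monolithic pipeline
        df.to_csv(fh, index=False, float_format="%.17g")


def dominant_clusters(labels: np.ndarray, types: list[str],
                      terminal_types: list[str],
                      pseudotime: np.ndarray | None = None,
                      allow_shared: bool = False) -> dict[str, int]:
    """Match each terminal population to the cluster it dominates.

    Candidate clusters for a terminal type are those where the type is
    the plurality type; when a type dominates no cluster (split across
    clusters led by other types) every cluster containing it becomes a
    candidate.  With ``pseudotime`` the latest-pseudotime candidate is
    preferred — the cluster at the branch *tip*, which is what one picks
    by eye when declaring leaf clusters — otherwise the candidate
    holding most of the type's cells.  Distinct clusters are assigned by
    maximum-weight matching; when the clustering has merged two terminal
    populations into one cluster no distinct assignment exists, and
    ``allow_shared`` lets such types share their best cluster (the
    resulting leaf set is then smaller than the type set) instead of
    raising.
    """
    types_arr = np.asarray(types)
    cluster_ids = np.unique(labels)
    plurality = {}
    for c in cluster_ids:
        vals, counts = np.unique(types_arr[labels == c], return_counts=True)
        plurality[int(c)] = vals[np.argmax(counts)]

    # maximum-weight bipartite assignment of types to distinct clusters:
    # candidates (plurality clusters) outrank mere containment, and the
    # score prefers the branch-tip (or largest) candidate
    from scipy.optimize import linear_sum_assignment

    FORBIDDEN = 1e12
    PENALTY = 1e6  # containment-only clusters rank below candidates
    cost = np.full((len(terminal_types), len(cluster_ids)), FORBIDDEN)
    for r, t in enumerate(terminal_types):
        if not (types_arr == t).any():
            raise ValueError(f"terminal type {t!r} has no cells in any cluster")
        for s, c in enumerate(cluster_ids):
            m = labels == c
            n_t = int((types_arr[m] == t).sum())
            if n_t == 0:
                continue
            score = float(pseudotime[m].mean()) if pseudotime is not None \
                else float(n_t)
            cost[r, s] = -score + (0 if plurality[int(c)] == t else PENALTY)
    rows, cols = linear_sum_assignment(cost)
    assigned = {int(r): int(s) for r, s in zip(rows, cols)}
    chosen: dict[str, int] = {}
    for r, t in enumerate(terminal_types):
        s = assigned.get(r)
        if s is not None and cost[r, s] < FORBIDDEN:
            chosen[t] = int(cluster_ids[s])
            continue
        if not allow_shared:
            raise ValueError(
                f"no distinct cluster available for terminal type {t!r}")
        # fall back to the type's best cluster even if already claimed
        valid = np.where(cost[r] < FORBIDDEN)[0]
        if len(valid) == 0:
            raise ValueError(f"terminal type {t!r} has no cells in any cluster")
        best_s = int(valid[np.argmin(cost[r][valid])])
        log.warning("terminal type %r shares cluster %d with another type",
                    t, int(cluster_ids[best_s]))
        chosen[t] = int(cluster_ids[best_s])
    return chosen


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    expr: mx.ExpressionMatrix
    pcs: mx.PCSpace
    clustering: Clustering
    tree: TrajectoryTree
    pseudotime: pd.DataFrame
    embedding_coords: np.ndarray | None = None
    trends: dict[int, pd.DataFrame] | None = None


def _load_or_simulate(config: RunConfig) -> tuple[mx.ExpressionMatrix, SimDataset | None]:
    if config.preset is not None:
        sim = preset(config.preset, seed=config.seed)
        return sim.to_expression_matrix(), sim
    if config.input_path is None:
        raise ValueError("config needs input_path or preset")
    return mx.load_matrix(config.input_path, config.input_format), None


def _infer_root_and_leaves(true_type: list[str], true_pseudotime: np.ndarray,
                           terminal_labels: list[str],
                           clustering: Clustering
                           ) -> tuple[int, list[LeafGroup]]:
    """Derive root/leaf clusters from simulator ground truth.

    Terminal types map to the clusters they dominate (singleton parallel
    groups); the root is the non-leaf cluster with the lowest mean true
    pseudotime.
    """
    leaves = dominant_clusters(clustering.labels, true_type, terminal_labels,
                               pseudotime=true_pseudotime, allow_shared=True)
    leaf_ids = set(leaves.values())
    means = {
        c: float(true_pseudotime[clustering.labels == c].mean())
        for c in clustering.cluster_ids if c not in leaf_ids
    }
    if not means:
        raise ValueError("every cluster was claimed as a leaf")
    root = min(means, key=lambda c: (means[c], c))
    groups = [LeafGroup([c], "parallel") for c in sorted(leaf_ids)]
    return root, groups


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write all artifacts."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    runlog: dict = {"config_hash": h, "seed": config.seed,
                    "parameters": config.model_dump()}

    expr, sim = _load_or_simulate(config)
    if write and sim is not None:
        _write_csv(sim.truth_frame(), outdir / "truth.csv", h)
        (outdir / "topology.json").write_text(sim.topology.to_json())
        (outdir / "topology.nwk").write_text(sim.topology.to_newick() + "\n")

    # --- preprocess -> PCA ------------------------------------------------
    if config.layer == "zscore":
        expr.layer = "zscore"
        scaled = expr
    else:
        norm = mx.filter_and_normalize(
            expr,
            min_features_per_cell=config.min_features_per_cell,
            min_cells_per_feature=config.min_cells_per_feature,
            scale_factor=config.scale_factor,
        )
        if config.n_hvg and config.n_hvg < norm.n_features:
            hvg = mx.select_hvg(norm, config.n_hvg)
            norm = mx.subset_features(norm, hvg)
        scaled = mx.scale_features(norm, clip=config.clip)
    pcs = mx.run_pca(scaled, n_components=config.n_pcs, seed=config.seed)
    if config.pc_selection is not None:
        pcs.n_selected = mx.select_components(
            pcs, config.pc_selection, config.cumvar_target)
    log.info("PCA: %d components, %d selected", pcs.coords.shape[1],
             pcs.n_selected)

    # --- graph + clustering ----------------------------------------------
    graph = build_knn_graph(pcs.selected, config.k)
    clustering = cluster_communities(graph, algorithm=config.algorithm,
                                     resolution=config.resolution,
                                     seed=config.seed)
    graph = bridge_components(graph)  # finite geodesics + cluster distances
    log.info("clustering: k=%d -> %d clusters", config.k,
             clustering.n_clusters)
    if write:
        _write_csv(clustering.to_frame(scaled.cell_ids),
                   outdir / "clusters.csv", h)
        _write_csv(
            pd.DataFrame(pcs.selected, columns=[
                f"PC{i + 1}" for i in range(pcs.n_selected)
            ]).assign(cell_id=scaled.cell_ids),
            outdir / "pcs.csv", h)

    # --- embedding --------------------------------------------------------
    emb = lisomap(graph, clustering, hubs_per_cluster=config.hubs_per_cluster,
                  dim=config.embedding_dim)
    if write:
        _write_csv(
            pd.DataFrame(emb.coords, columns=["x", "y", "z"][:config.embedding_dim]
                         ).assign(cell_id=scaled.cell_ids),
            outdir / "embedding.csv", h)

    # --- trajectory tree --------------------------------------------------
    root = config.root
    groups = [LeafGroup(list(g.members), g.structure)
              for g in config.leaf_groups]
    if (root is None or not groups):
        if sim is None:
            raise ValueError("config must name a root cluster and leaf groups")
        # align ground truth with the cells surviving QC filtering
        pos = {cid: i for i, cid in enumerate(sim.cell_ids)}
        kept = [pos[c] for c in scaled.cell_ids]
        root, groups = _infer_root_and_leaves(
            [sim.true_type[i] for i in kept], sim.true_pseudotime[kept],
            sim.topology.leaves, clustering)
        log.info("inferred root=%d leaves=%s", root,
                 [g.member_clusters for g in groups])
    cg = cluster_distances(graph, clustering)
    tree = spanning_tree(cg, root, groups)
    for msg in tree.validation:
        log.warning("tree validation: %s", msg)
    runlog["tree_validation"] = tree.validation
    if write:
        (outdir / "tree.json").write_text(tree.to_json())
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        try:
            import networkx as nx

            nx.write_graphml(tree.to_networkx(), outdir / "tree.graphml")
        except Exception as exc:  # pragma: no cover
            log.warning("graphml export failed: %s", exc)

    # --- pseudotime -------------------------------------------------------
    assign = map_cells(tree, clustering, pcs.selected)
    pt = assign.to_frame(scaled.cell_ids)
    if write:
        _write_csv(pt, outdir / "pseudotime.csv", h)

    # --- trend analysis per branch ---------------------------------------
    trends: dict[int, pd.DataFrame] = {}
    for leaf in tree.leaves():
        cells = branch_cells(assign, tree, leaf)
        if len(cells) < 8:
            log.warning("branch to leaf %d has %d cells; skipping PTA",
                        leaf, len(cells))
            continue
        bm = bin_branch(cells, scaled, assign.pseudotime, config.n_bins)
        bm.branch = str(leaf)
        res = pta(bm, n_ranks=config.n_ranks,
                  lambda_sparse=config.lambda_sparse,
                  lambda_smooth=config.lambda_smooth)
        tdf = pd.DataFrame({"bin_pseudotime": bm.bin_pseudotime})
        for r, rk in enumerate(res.ranks, start=1):
            tdf[f"rank{r}"] = rk.d * rk.trend
        trends[leaf] = tdf
        if write:
            _write_csv(tdf, outdir / f"trend_leaf{leaf}.csv", h)
            _write_csv(res.to_frame(), outdir / f"scores_leaf{leaf}.csv", h)

    if write:
        (outdir / "run_log.json").write_text(
            json.dumps(runlog, indent=1, sort_keys=True, default=str))
    return PipelineResult(expr=expr, pcs=pcs, clustering=clustering,
                          tree=tree, pseudotime=pt,
                          embedding_coords=emb.coords, trends=trends)
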