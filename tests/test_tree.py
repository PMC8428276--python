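import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import floyd_warshall

from treetrace.graph import CellGraph, Clustering
from treetrace.tree import (ClusterGraph, LeafGroup, TrajectoryTree,
                            attach_leaf_groups, build_backbone,
                            cluster_distances, exploratory_mst, spanning_tree)


def _cell_graph(n, edges, coords=None):
    rows, cols, vals = zip(*edges)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)
    if coords is None:
        coords = np.zeros((n, 2))
    return CellGraph(adjacency=A, k_used=0, coords=np.asarray(coords, float))


def _clustering(labels, coords):
    labels = np.asarray(labels)
    cents = {int(c): coords[labels == c].mean(axis=0)
             for c in np.unique(labels)}
    return Clustering(labels=labels, centroids=cents, algorithm="leiden",
                      k_used=0, seed=0)


def _cluster_graph(dist, clusters=None, centroids=None):
    """ClusterGraph from a symmetric single-hop distance matrix with
    np.inf where clusters are unjoined."""
    dist = np.asarray(dist, dtype=float)
    C = dist.shape[0]
    clusters = clusters or list(range(1, C + 1))
    adj = np.where(np.isfinite(dist), dist, 0.0)
    gd = floyd_warshall(sp.csr_matrix(adj), directed=False)
    cents = centroids if centroids is not None \
        else {c: np.zeros(2) for c in clusters}
    return ClusterGraph(clusters=clusters, neighbor_dist=dist,
                        graph_dist=np.asarray(gd), centroids=cents)


class TestClusterDistances:
    def test_mean_of_joining_edges(self):
        g = _cell_graph(4, [(0, 2, 1.0), (1, 3, 3.0)])
        cl = _clustering([1, 1, 2, 2], g.coords)
        cg = cluster_distances(g, cl)
        assert cg.neighbor_dist[0, 1] == pytest.approx(2.0)

    def test_two_hop_graph_distance(self):
        # clusters A-B-C in a chain, no direct A-C edge
        g = _cell_graph(6, [(0, 2, 1.5), (3, 4, 2.5)])
        cl = _clustering([1, 1, 2, 2, 3, 3], g.coords)
        cg = cluster_distances(g, cl)
        assert not np.isfinite(cg.neighbor_dist[0, 2])
        assert cg.graph_dist[0, 2] == pytest.approx(1.5 + 2.5)

    def test_matches_floyd_warshall_oracle(self, rng):
        n, C = 40, 5
        coords = rng.normal(size=(n, 3))
        labels = rng.integers(1, C + 1, size=n)
        labels[:C] = np.arange(1, C + 1)  # every cluster populated
        pairs = {(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.2}
        g = _cell_graph(n, [(i, j, float(np.linalg.norm(coords[i] - coords[j])))
                            for i, j in pairs], coords)
        cl = _clustering(labels, coords)
        cg = cluster_distances(g, cl)
        adj = np.where(np.isfinite(cg.neighbor_dist), cg.neighbor_dist, 0.0)
        oracle = floyd_warshall(sp.csr_matrix(adj), directed=False)
        np.testing.assert_allclose(cg.graph_dist, oracle, atol=1e-12)

    def test_symmetry_zero_diagonal(self, rng):
        coords = rng.normal(size=(20, 2))
        pairs = [(i, j, 1.0 + rng.random()) for i in range(20)
                 for j in range(i + 1, 20) if rng.random() < 0.3]
        g = _cell_graph(20, pairs, coords)
        cl = _clustering(rng.integers(1, 4, 20), coords)
        cg = cluster_distances(g, cl)
        np.testing.assert_allclose(cg.neighbor_dist, cg.neighbor_dist.T)
        assert np.all(np.diag(cg.graph_dist) == 0)


class TestBackbone:
    def test_line_connects_at_k3(self):
        d = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1],
                      [3, 2, 1, 0]], dtype=float)
        cg = _cluster_graph(d)
        bb = build_backbone(cg, root=1, leaf_clusters=set())
        # all 4 on one component
        nodes = {c for e in bb for c in e}
        assert nodes == {1, 2, 3, 4}

    def test_k_grows_until_connected(self):
        # two tight pairs far apart: at k=3 within 5 nodes the pairs see
        # each other eventually; engineered so k must grow
        d = np.full((6, 6), 100.0)
        np.fill_diagonal(d, 0.0)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            d[i, j] = d[j, i] = 1.0
        cg = _cluster_graph(d)
        bb = build_backbone(cg, root=1, leaf_clusters=set())
        # resulting graph must be connected
        import networkx as nx

        G = nx.Graph(list(bb))
        G.add_nodes_from(range(1, 7))
        assert nx.is_connected(G)

    def test_degenerate_single_nonleaf(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        cg = _cluster_graph(d)
        assert build_backbone(cg, root=1, leaf_clusters={2}) == {}

    def test_root_in_leaves_rejected(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        cg = _cluster_graph(d)
        with pytest.raises(ValueError):
            build_backbone(cg, root=1, leaf_clusters={1})


class TestLeafGroups:
    def _setup(self):
        # clusters 1..3 backbone line, clusters 4..8 leaf candidates
        C = 8
        d = np.full((C, C), np.inf)
        np.fill_diagonal(d, 0.0)
        def set_d(a, b, v):
            d[a - 1, b - 1] = d[b - 1, a - 1] = v
        set_d(1, 2, 1.0)
        set_d(2, 3, 1.0)
        set_d(3, 4, 1.0)
        set_d(4, 5, 1.0)
        set_d(5, 6, 1.5)
        set_d(4, 7, 4.0)
        set_d(4, 8, 2.5)
        return _cluster_graph(d)

    def test_single_member_group_all_structures(self):
        cg = self._setup()
        bb = build_backbone(cg, 1, {4})
        for structure in ("linear", "parallel", "mst"):
            aug = attach_leaf_groups(bb, cg, [LeafGroup([4], structure)],
                                     [1, 2, 3])
            new = set(aug) - set(bb)
            assert new == {(3, 4)}

    def test_linear_chain_order(self):
        cg = self._setup()
        leafs = {4, 5, 6}
        bb = build_backbone(cg, 1, leafs)
        grp = LeafGroup([5, 6, 4], "linear")
        aug = attach_leaf_groups(bb, cg, [grp], [1, 2, 3])
        assert grp.connector == 4
        chain_edges = set(aug) - set(bb)
        assert chain_edges == {(3, 4), (4, 5), (5, 6)}

    def test_mst_group_matches_prim_oracle(self, rng):
        C = 8
        pts = rng.normal(size=(C, 2)) * 3
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        cg = _cluster_graph(d)
        members = [4, 5, 6, 7, 8]
        bb = build_backbone(cg, 1, set(members))
        grp = LeafGroup(members, "mst")
        aug = attach_leaf_groups(bb, cg, [grp], [1, 2, 3])
        got = {e for e in set(aug) - set(bb)
               if e[0] in members and e[1] in members}
        # Prim oracle over the member submatrix
        idx = {m: cg.index(m) for m in members}
        intree = {members[0]}
        oracle = set()
        while len(intree) < len(members):
            best = min(((cg.graph_dist[idx[a], idx[b]], a, b)
                        for a in intree for b in members if b not in intree))
            _, a, b = best
            oracle.add((min(a, b), max(a, b)))
            intree.add(b)
        assert got == oracle


class TestSpanningTree:
    def test_chain_root_mid_leaf(self):
        d = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        cg = _cluster_graph(d)
        t = spanning_tree(cg, 1, [LeafGroup([3])])
        assert set((p, c) for p, c, _ in t.edges) == {(1, 2), (2, 3)}
        assert t.degree(3) == 1 and t.leaf_flags[3]

    def test_structured_instance_with_mst_group(self, rng):
        """A 17-cluster instance with one 5-member MST leaf group and five
        singleton leaf groups yields a valid tree: singleton leaves are
        pendant and the group's internal MST joins its members."""
        pts = rng.normal(size=(17, 2)) * 2 + \
            np.linspace(0, 10, 17)[:, None]
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        cg = _cluster_graph(d)
        mst_members = [2, 6, 8, 9, 10]
        singletons = [5, 3, 12, 16, 11]
        groups = [LeafGroup(mst_members, "mst")] + \
            [LeafGroup([c]) for c in singletons]
        t = spanning_tree(cg, 17, groups)
        assert len(t.edges) == len(t.nodes) - 1
        for c in singletons:
            assert t.degree(c) == 1
        # the MST substructure is present: members form a connected
        # subtree among themselves plus one connector edge outward
        internal = [(p, c) for p, c, _ in t.edges
                    if p in mst_members and c in mst_members]
        assert len(internal) == 4

    def test_path_lengths_match_dijkstra_oracle(self, rng):
        C = 8
        pts = rng.normal(size=(C, 2)) * 4
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        cg = _cluster_graph(d)
        leaves = [6, 7, 8]
        groups = [LeafGroup([c]) for c in leaves]
        t = spanning_tree(cg, 1, groups)

        # oracle: Dijkstra on the same augmented graph
        from treetrace.tree import _dijkstra_tree, build_backbone as bb_fn
        bb = bb_fn(cg, 1, set(leaves))
        aug = attach_leaf_groups(bb, cg, [LeafGroup([c]) for c in leaves],
                                 [c for c in cg.clusters if c not in leaves])
        nodes = sorted({1} | {c for e in aug for c in e} | set(leaves))
        _, dist = _dijkstra_tree(nodes, aug, 1)
        for leaf in leaves:
            path = t.path_to(leaf)
            length = sum(t.edge_length(a, b)
                         for a, b in zip(path, path[1:]))
            assert length == pytest.approx(dist[leaf])

    def test_unreachable_leaf_raises(self):
        d = np.array([[0, 1, np.inf], [1, 0, np.inf], [np.inf, np.inf, 0]])
        cg = _cluster_graph(d, centroids={})
        with pytest.raises(ValueError, match="unreachable"):
            spanning_tree(cg, 1, [LeafGroup([3])])

    def test_tree_invariants_random_instances(self, rng):
        for trial in range(5):
            C = int(rng.integers(6, 11))
            pts = rng.normal(size=(C, 3)) * 3
            d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
            cg = _cluster_graph(d)
            leaves = list(rng.choice(np.arange(2, C + 1), 2, replace=False))
            t = spanning_tree(cg, 1, [LeafGroup([int(c)]) for c in leaves])
            assert len(t.edges) == len(t.nodes) - 1
            for c in leaves:
                assert t.degree(int(c)) == 1
            # connectivity: every node reaches the root
            for n in t.nodes:
                assert t.path_to(n)[0] == t.root


class TestExploratoryMST:
    def test_forced_triangle(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        cg = _cluster_graph(d)
        edges = exploratory_mst(cg)
        assert {(a, b) for a, b, _ in edges} == {(1, 2), (1, 3)}

    def test_idempotent_on_tree_metric(self):
        # distances generated by a path 1-2-3-4 with unit edges
        d = np.abs(np.subtract.outer(np.arange(4), np.arange(4))).astype(float)
        cg = _cluster_graph(d)
        edges = exploratory_mst(cg)
        assert {(a, b) for a, b, _ in edges} == {(1, 2), (2, 3), (3, 4)}

    def test_weight_matches_exhaustive_enumeration(self, rng):
        """MST weight over 7 clusters equals the minimum over all 16807
        labeled spanning trees (Pruefer enumeration)."""
        n = 7
        pts = rng.normal(size=(n, 2)) * 5
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        cg = _cluster_graph(d)
        got = sum(w for _, _, w in exploratory_mst(cg))

        def tree_from_pruefer(seq):
            degree = [1] * n
            for v in seq:
                degree[v] += 1
            edges = []
            ptr = iter(sorted(range(n)))
            leaves = [v for v in range(n) if degree[v] == 1]
            import heapq

            heapq.heapify(leaves)
            for v in seq:
                leaf = heapq.heappop(leaves)
                edges.append((leaf, v))
                degree[v] -= 1
                if degree[v] == 1:
                    heapq.heappush(leaves, v)
            a, b = heapq.heappop(leaves), heapq.heappop(leaves)
            edges.append((a, b))
            return edges

        best = np.inf
        for seq in itertools.product(range(n), repeat=n - 2):
            w = sum(d[a, b] for a, b in tree_from_pruefer(list(seq)))
            best = min(best, w)
        assert got == pytest.approx(best)


class TestTreeSerialization:
    def _tree(self):
        return TrajectoryTree(
            nodes=[1, 2, 3, 4],
            edges=[(1, 2, 1.0), (2, 3, 2.0), (2, 4, 0.5)],
            root=1,
            leaf_flags={1: False, 2: False, 3: True, 4: True},
            provenance={1: "backbone", 2: "backbone", 3: "leaf", 4: "leaf"},
        )

    def test_json_round_trip(self):
        t = self._tree()
        back = TrajectoryTree.from_json(t.to_json())
        assert back.edges == t.edges
        assert back.root == t.root
        assert back.leaf_flags == t.leaf_flags

    def test_newick_parses(self):
        from io import StringIO

        from Bio import Phylo

        t = self._tree()
        tree = Phylo.read(StringIO(t.to_newick()), "newick")
        assert tree.count_terminals() == 2

    def test_bifurcations_and_collapse(self):
        t = self._tree()
        assert t.bifurcations() == [2]
        # chain 1-2 collapses onto the branch point
        assert len(t.collapsed_branches()) == 3

    def test_root_with_two_children_is_branch_point(self):
        t = TrajectoryTree(
            nodes=[1, 2, 3], edges=[(1, 2, 1.0), (1, 3, 1.0)], root=1,
            leaf_flags={1: False, 2: True, 3: True},
            provenance={1: "backbone", 2: "leaf", 3: "leaf"})
        assert t.bifurcations() == [1]
        assert len(t.collapsed_branches()) == 2
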