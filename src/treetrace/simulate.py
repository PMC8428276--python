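"""Branching-lineage count simulator with ground truth.

Generates tree-structured single-cell counts in the style of
branching-process simulators: a small number of latent expression
programs perform a random walk along pseudotime, walks diverge
independently after every branch point, gene means are log-linear in the
program activities through a sparse nonnegative gene-program weight
matrix, and counts are negative-binomial around a per-cell log-normal
library-size factor.  Cells are placed uniformly along their branch.

All randomness flows through a counter-based bit generator (Philox), so
a given seed yields the identical stream on any platform.

Two presets reproduce standard evaluation designs: ``rare_lineage``
(seven populations, one rare terminal type of 15 cells, 0.78% of 1,915)
and ``six_bifurcations`` (1,300 cells x 500 genes on a tree with 7
leaves and 13 branches, library factor log-normal with scale 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimTopology:
    """A rooted branching topology; each edge is one named branch.

    ``edges`` maps branch label -> (parent label, length in pseudotime
    steps).  The root label has no edge.  Branch labels double as the
    cell-type labels of cells sampled on that branch.
    """

    root: str
    edges: dict[str, tuple[str, int]]  # child -> (parent, steps)

    def __post_init__(self) -> None:
        labels = set(self.edges) | {self.root}
        for child, (parent, steps) in self.edges.items():
            if parent not in labels:
                raise ValueError(f"parent {parent!r} of {child!r} undefined")
            if child == self.root:
                raise ValueError("root cannot have a parent edge")
            if steps < 2:
                raise ValueError(f"branch {child!r} shorter than 2 steps")
        # acyclicity / single root: walk each node up to the root
        for child in self.edges:
            seen = {child}
            cur = child
            while cur != self.root:
                cur = self.edges[cur][0]
                if cur in seen:
                    raise ValueError(f"cycle through {child!r}")
                seen.add(cur)

    @property
    def branches(self) -> list[str]:
        return sorted(self.edges)

    @property
    def leaves(self) -> list[str]:
        parents = {p for p, _ in self.edges.values()}
        return sorted(b for b in self.edges if b not in parents)

    def children(self, label: str) -> list[str]:
        return sorted(c for c, (p, _) in self.edges.items() if p == label)

    def start_time(self, branch: str) -> int:
        """Pseudotime step at which ``branch`` begins (root = 0)."""
        t = 0
        parent = self.edges[branch][0]
        while parent != self.root:
            t += self.edges[parent][1]
            parent = self.edges[parent][0]
        return t

    def to_newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children(node)
            inner = ""
            if kids:
                inner = "(" + ",".join(
                    f"{rec(c)}:{self.edges[c][1]}" for c in kids) + ")"
            return f"{inner}{node}"
        return rec(self.root) + ";"

    def to_json(self) -> str:
        return json.dumps({
            "root": self.root,
            "edges": {c: {"parent": p, "steps": s}
                      for c, (p, s) in self.edges.items()},
        }, indent=1, sort_keys=True)


@dataclass
class SimDataset:
    """Simulated counts plus full ground truth."""

    counts: np.ndarray  # cells x genes, integer
    true_pseudotime: np.ndarray
    true_branch: list[str]
    true_type: list[str]
    library_factor: np.ndarray
    topology: SimTopology
    seed: int
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.counts.shape[0])]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.counts.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def to_expression_matrix(self):
        from .matrix import ExpressionMatrix

        return ExpressionMatrix(self.counts.astype(float), list(self.cell_ids),
                                list(self.gene_ids), layer="counts")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "type": self.true_type,
            "branch": self.true_branch,
            "pseudotime": self.true_pseudotime,
            "library_factor": self.library_factor,
        })


def make_topology(edges: list[tuple[str, str, int]], root: str) -> SimTopology:
    """Validate an (parent, child, steps) edge list into a topology."""
    emap: dict[str, tuple[str, int]] = {}
    for parent, child, steps in edges:
        if child in emap:
            raise ValueError(f"{child!r} has two parents")
        emap[child] = (parent, int(steps))
    return SimTopology(root=root, edges=emap)


def simulate(
    topology: SimTopology,
    cells_per_type: dict[str, int],
    n_genes: int = 500,
    n_programs: int = 8,
    branch_drift: float = 2.5,
    program_walk_sd: float = 0.05,
    dispersion: float = 10.0,
    libsize_sigma: float = 0.7,
    seed: int = 0,
    base_mean: float = 2.0,
) -> SimDataset:
    """Draw a tree-structured count dataset with ground truth.

    Program activities W_k(t) evolve along pseudotime as a directed
    random walk: each branch commits to its own random drift direction
    in program space (total drift norm ``branch_drift`` over the
    branch), modelling persistent activation of fate-specific programs,
    plus per-step diffusion of sd ``program_walk_sd``.  Children inherit
    the parent's endpoint state and fork independently, so sibling
    lineages diverge along different directions — the straight radiating
    arms characteristic of branching differentiation.  Gene means are
    ``base_g * exp(sum_k H_gk W_k(t))`` with H a sparse nonnegative
    gene-program weight matrix; counts are negative-binomial with shape
    ``dispersion`` (variance m + m^2/dispersion; ``np.inf`` gives
    Poisson) scaled by a per-cell LogNormal(0, ``libsize_sigma``)
    library factor.  Cells are placed uniformly along their type's
    branch.
    """
    unknown = set(cells_per_type) - set(topology.branches)
    if unknown:
        raise ValueError(f"unknown cell types {sorted(unknown)}")
    rng = np.random.Generator(np.random.Philox(seed))

    # sparse nonnegative gene-program weights: each gene loads on 1-2 programs
    H = np.zeros((n_genes, n_programs))
    primary = rng.integers(0, n_programs, size=n_genes)
    H[np.arange(n_genes), primary] = rng.gamma(2.0, 0.5, size=n_genes)
    extra = rng.random(n_genes) < 0.3
    secondary = rng.integers(0, n_programs, size=n_genes)
    H[np.arange(n_genes)[extra], secondary[extra]] += rng.gamma(
        2.0, 0.25, size=int(extra.sum()))
    base = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)

    # directed program walks per branch, inheriting the parent's endpoint
    walks: dict[str, np.ndarray] = {}  # branch -> (steps+1) x K
    def grow(branch: str, start: np.ndarray) -> None:
        steps = topology.edges[branch][1]
        direction = rng.normal(0.0, 1.0, size=n_programs)
        direction *= branch_drift / max(np.linalg.norm(direction), 1e-12)
        incr = direction / steps + rng.normal(
            0.0, program_walk_sd, size=(steps, n_programs))
        path = np.vstack([start, start + np.cumsum(incr, axis=0)])
        walks[branch] = path
        for child in topology.children(branch):
            grow(child, path[-1])

    origin = np.zeros(n_programs)
    for child in topology.children(topology.root):
        grow(child, origin)

    cells_t, cells_branch = [], []
    for btype in sorted(cells_per_type):
        n = cells_per_type[btype]
        steps = topology.edges[btype][1]
        pos = np.sort(rng.random(n)) * steps
        cells_t.extend(pos)
        cells_branch.extend([btype] * n)
    n_cells = len(cells_t)
    if n_cells == 0:
        raise ValueError("no cells requested")

    lib = rng.lognormal(0.0, libsize_sigma, size=n_cells) if libsize_sigma > 0 \
        else np.ones(n_cells)

    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    ptime = np.empty(n_cells)
    for i, (pos, br) in enumerate(zip(cells_t, cells_branch)):
        path = walks[br]
        steps = topology.edges[br][1]
        # linear interpolation of the walk at the cell's position
        lo = min(int(np.floor(pos)), steps - 1)
        frac = pos - lo
        W = (1 - frac) * path[lo] + frac * path[lo + 1]
        mean = lib[i] * base * np.exp(np.clip(H @ W, -20, 20))
        if np.isinf(dispersion):
            counts[i] = rng.poisson(mean)
        else:
            counts[i] = rng.poisson(rng.gamma(dispersion, mean / dispersion))
        ptime[i] = topology.start_time(br) + pos

    return SimDataset(
        counts=counts,
        true_pseudotime=ptime,
        true_branch=list(cells_branch),
        true_type=list(cells_branch),
        library_factor=lib,
        topology=topology,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def rare_lineage_topology(steps: int = 40) -> SimTopology:
    """Seven populations A-G; E is a short rare side branch."""
    return make_topology([
        ("root", "A", steps),
        ("A", "B", steps),
        ("B", "C", steps),
        ("B", "E", steps),
        ("C", "D", steps),
        ("D", "F", steps),
        ("D", "G", steps),
    ], root="root")


def six_bifurcations_topology(steps: int = 40) -> SimTopology:
    """Thirteen branches b0..b12 with six bifurcations and seven leaves."""
    return make_topology([
        ("root", "b0", steps),
        ("b0", "b1", steps), ("b0", "b2", steps),
        ("b1", "b3", steps), ("b1", "b4", steps),
        ("b2", "b5", steps), ("b2", "b6", steps),
        ("b3", "b7", steps), ("b3", "b8", steps),
        ("b4", "b9", steps), ("b4", "b10", steps),
        ("b5", "b11", steps), ("b5", "b12", steps),
    ], root="root")


PRESETS = ("rare_lineage", "six_bifurcations")


def preset(name: str, seed: int = 0) -> SimDataset:
    """Standard evaluation datasets.

    ``rare_lineage``: 1,915 cells — 300 each in types A-D, 350 in F and
    G, and 15 in the rare terminal type E (0.78% of all cells).
    ``six_bifurcations``: 1,300 cells x 500 genes spread evenly over 13
    branches (7 leaves), library-size factor LogNormal(0, 0.7).
    """
    if name == "rare_lineage":
        topo = rare_lineage_topology()
        return simulate(
            topo,
            cells_per_type={"A": 300, "B": 300, "C": 300, "D": 300,
                            "E": 15, "F": 350, "G": 350},
            n_genes=500,
            libsize_sigma=0.7,
            seed=seed,
        )
    if name == "six_bifurcations":
        topo = six_bifurcations_topology()
        cells = {b: 100 for b in topo.branches}
        return simulate(topo, cells_per_type=cells, n_genes=500,
                        libsize_sigma=0.7, seed=seed)
    raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
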