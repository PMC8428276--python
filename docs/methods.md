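# Methods

`treetrace` reconstructs a developmental trajectory as a rooted tree over
cell clusters, places every cell on that tree to obtain a pseudotime, and
summarizes expression change along each root-to-leaf branch by sparse,
smooth principal trends.  This note records the model choices, the
defaults and why they hold, and what the bundled simulator does and does
not capture.

## Preprocessing and dimension reduction

Raw counts are filtered (cells with fewer than `min_features_per_cell`
detected features, default 200, then features detected in fewer than
`min_cells_per_feature` cells, default 3 — cells first, features second),
library-size normalized to `scale_factor` (default 10^4) counts per cell,
and log1p-transformed.  Highly variable features are ranked by the
residual of a quadratic fit of log variance against log mean; constant
features rank last by construction.  Features are then standardized
(zero mean, unit variance, clipped at ±10 by default; zero-variance
features map to zero).  Externally produced z-score matrices (e.g.
accessibility deviation scores) carry the `zscore` layer tag and skip
normalization and scaling entirely, feeding PCA directly.

PCA uses a full SVD with a fixed sign convention (the largest-magnitude
loading of each component is positive) so embeddings and trees are
reproducible.  The number of retained components can be chosen by the
scree elbow (maximum perpendicular distance to the chord) or by a
cumulative-variance target; the pipeline default is simply the requested
`n_pcs`, because component choice is ultimately a judgment call the user
can override.

The cell-level QC threshold is not cosmetic on simulated data: with
log-normal library factors of scale 0.7, roughly a sixth of cells have
less than half the median depth.  After normalization those cells are
dominated by sampling noise and form diffuse clusters running parallel
to the trajectory; left in place they distort the cluster graph (see
below).  Removing low-complexity cells is the standard remedy and is
applied by default.

## Graph, clustering, and the k sweep

A kNN graph is built in the selected PC space, symmetrized by union (a
rare cell that appears in others' neighbor lists stays connected even
when its own neighbors point elsewhere), with Euclidean edge weights and
distance ties broken by lower cell index.  Communities are found by
Leiden (default) or Louvain on the unweighted topology with resolution
1.0; cluster IDs are relabeled 1..C by decreasing size.  Because the
partition depends on k, `sweep_k` runs the whole clustering across
k = 4..20 and tabulates cluster counts; smaller k fragments the graph
more and is the regime in which rare populations can appear as their own
clusters.  The choice among sweep results is left to the caller.

If the kNN graph is disconnected, components are bridged by repeatedly
adding the single shortest inter-component Euclidean edge.  Bridging is
required for finite landmark geodesics and finite cluster distances; it
is done after clustering so bridge edges never influence community
detection.

## 3-D landmark ISOMAP

Within each cluster the cells with the most intra-cluster kNN
connections ("graph hubs") serve as landmarks — hubs sit centrally and
give stable geodesics.  One hub per cluster is the default,
auto-raised until at least max(10, n_clusters, dim+2) landmarks exist.
Geodesic distances are computed landmark-first: one Dijkstra search per
landmark over the bridged graph, which is what makes the method cheap
(L × n distances rather than n × n); the searches are independent and
order-invariant.  Classical metric MDS on the double-centered squared
landmark-landmark block gives landmark coordinates; all other cells are
triangulated from their squared distances to the landmarks via the
pseudo-inverse projection against the landmark column means.  Negative
eigenvalues (geodesics are not exactly Euclidean) are truncated at
zero; axes are eigenvalue-ordered and sign-fixed.  The `stress` field
reports the relative residual between geodesic and embedded distances
over landmark pairs.  With every cell a landmark the construction
reduces exactly to classical ISOMAP (tested up to an orthogonal
transform at 1e-6).

## Cluster distances and the rooted spanning tree

Step 1 — distances.  For every pair of clusters joined by cell-level
kNN edges, the neighbor distance is the mean length of those joining
edges; unjoined pairs are missing (treated as infinite).  A pair only
counts as joined when supported by at least max(3, 0.1·min cluster
size) joining edges: genuinely adjacent populations share a boundary
and are connected by edges from a sizable fraction of their cells (tens
of edges in practice), whereas a handful of noisy cells can bridge
unrelated clusters, and such spurious contacts would let cluster-level
shortest paths skip real intermediate populations.  If the support
threshold disconnects the cluster graph, the strongest dropped
connections are restored until it reconnects.  The graph distance is
the all-pairs shortest path over neighbor distances.

Step 2 — backbone and leaves.  The user names a root cluster and leaf
groups (terminal clusters with `linear`, `parallel`, or `mst` internal
structure).  A kNN graph over the non-leaf clusters is grown from k = 3
until connected (metric: graph distance).  Each leaf group attaches
through its connector — the member closest to any non-leaf cluster —
to that nearest non-leaf cluster; `parallel` members each link to the
attachment cluster independently, `linear` members chain in order of
increasing graph distance from the attachment, `mst` members join by
their internal minimum spanning tree.

Step 3 — tree.  Shortest paths from the root to every declared leaf
cluster are traced through the augmented graph and their union is the
trajectory.  Two deterministic tie-breaks matter.  Backbone edge
weights are themselves shortest-path distances, so a one-hop shortcut
and the multi-hop route through intermediate clusters often have
exactly equal length; ties prefer the path with more hops — keeping
intermediate clusters on the trajectory — and then the smallest
predecessor id.  Non-leaf clusters that end up on no path are, by
default, merged into their nearest on-tree non-leaf cluster (recorded
in `tree.merged`): this respects the rule that non-leaf tree nodes have
degree at least two and keeps branch statistics clean.  The alternative
`isolated="attach"` keeps them as pendant nodes flagged
`attached_isolated`; pendant nodes violate the degree rule and inflate
bifurcation and branch counts, which the validation report records.

An unrooted exploratory MST over graph distances is available when no
prior root/leaf knowledge exists.

Branch points are nodes with at least two children (equal to degree ≥ 3
for non-root nodes; a root with two children also splits the lineage).
`collapsed_branches` collapses chains of single-child nodes and returns
one edge per maximal segment between the root, branch points, and
terminal nodes — the biological branches of the trajectory.

## Pseudotime

Each cell is assigned to a tree edge incident to its own cluster: the
cell is projected orthogonally onto the segment joining the two
endpoint-cluster centroids in PC space (offset clamped to [0, 1]), and
among candidate edges the one with the smallest perpendicular residual
wins.  Pseudotime is the cumulative edge length from the root to the
projected position; cells of merged clusters are treated as members of
their host cluster.  Branch membership for downstream analysis is a
path test: a cell belongs to the branch of leaf L when its edge lies on
the root→L path.  Raw cumulative lengths are exported along with an
optional [0, 1]-normalized column for display.

## Principal trend analysis

Cells on a branch, ordered by pseudotime, are averaged into contiguous
equal-count bins (default min(100, branch size); remainder spread over
the leading bins) — neighbor averaging reduces noise and run time.  On
the resulting genes × bins matrix X, rank-one trends are extracted by
alternating optimization of X ≈ d·u·vᵀ:

- gene scores u: soft-threshold(X v, λ₁), renormalized — the L1 penalty
  zeroes most genes, leaving a sparse per-gene contribution score;
- trend v: solve (I + λ₂·D₂ᵀD₂) v = Xᵀ u with D₂ the second-difference
  operator, renormalized — the roughness penalty makes the trend a
  smooth curve over pseudotime;
- magnitude d = uᵀ X v; iterate from the leading singular pair until
  the relative change in d falls below 1e-6.

λ₂ defaults to the generalized-cross-validation minimizer of the ridge
smoother on the bin axis; λ₁ defaults to the universal threshold
σ̂·sqrt(2 log g), with σ̂ the MAD estimate of the noise scale of X v, so
genes whose projection is consistent with noise get exactly zero score.
A saturating penalty yields a flagged null trend.  Trends are
sign-fixed to rise overall (endpoint difference non-negative), with
scores flipped accordingly.  Further ranks come from deflation
(X ← X − d·u·vᵀ); three ranks are the conventional default.  Whether
the original formulation couples ranks jointly rather than by deflation
is not recoverable; deflation is used.  Per-rank variance explained is
each rank's own share of the original squared Frobenius norm, and the
residual norm strictly decreases across accepted ranks.

Planted-model recovery (support of a sparse gene set, cosine > 0.95 to
a planted smooth trend, across seeds) is the acceptance surface for
this component; published real-data score values depend on datasets not
shipped here.

## The simulator

The generator emulates tree-structured differentiation with a known
topology, pseudotime, and labels.  K latent expression programs (default
8) evolve along pseudotime as a *directed* random walk: each branch
commits to its own random drift direction in program space with total
drift norm `branch_drift` (default 2.5 log-units over the branch),
plus per-step diffusion of sd `program_walk_sd` (default 0.05).
Children inherit the parent's endpoint state and fork independently, so
sibling lineages diverge along different directions — the straight
radiating arms characteristic of branching differentiation data.  The
directed walk is deliberate: a pure-diffusion walk leaves sibling
branches entangled near every branch point and produces data whose
topology no clustering-based method can recover, which is not the
regime branching-process simulators are built to emulate.

Gene means are base_g · exp(H W(t)) with H a sparse nonnegative
gene-program weight matrix (each gene loads on one, sometimes two,
programs) and base_g log-normal around `base_mean` (default 2).  Counts
are negative-binomial via the gamma-Poisson mixture with shape
`dispersion` (default 10, i.e. variance ≈ 2× mean at mean 10;
`inf` gives Poisson), scaled by a per-cell LogNormal(0,
`libsize_sigma`) library factor.  Cells are placed uniformly along
their type's branch; branch lengths default to 40 pseudotime steps.
All randomness flows through a counter-based Philox generator, so a
seed fully determines the dataset across platforms.

Two presets encode the standard evaluation designs: `rare_lineage`
(1,915 cells: 300 each in types A–D, 350 in F and G, 15 in the rare
terminal type E — 0.78% of cells) and `six_bifurcations` (1,300 cells ×
500 genes uniformly over a 13-branch, 7-leaf tree, library scale 0.7).

What the simulator does not capture: dropout beyond NB sampling,
batch effects, doublets, cell-cycle structure, or uneven sampling along
branches.  Passing tests on these data show the pipeline recovers
topology, pseudotime, and planted trends under controlled branching
structure with realistic depth noise — not that it handles every
artifact of real experiments.  One known limitation: a rare terminal
population (15 cells of ~2,000) contributes so little variance that its
direction can drop out of a 10-PC representation; isolating such
populations requires more components or a dedicated rare-type
clustering, as the underlying method's own protocol acknowledges by
exposing k (small k favors rare clusters).

## Problem sizes and numerical notes

The bundled evaluation runs the full pipeline on 1,300 × 500 count
matrices (seconds per seed on one core); topology-recovery statistics
take the majority over 5 seeds.  Oracle-equivalence tests run on 30–60
point instances where exhaustive algorithms (Floyd–Warshall, Prüfer
enumeration of all labeled spanning trees, brute-force modularity over
all set partitions of 10 nodes) are feasible.  Edge-length ties are
broken deterministically everywhere; BLAS results vary in the final
bits with memory alignment, so cross-route comparisons (staged CLI vs
monolithic pipeline) assert identical topology and lengths to 1e-9
relative rather than byte identity, while same-route reruns are
byte-identical.
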