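"""Principal trend analysis (PTA) along a trajectory branch.

Cells on a branch are averaged into contiguous pseudotime bins, giving a
genes x bins matrix X.  PTA then extracts smooth, sparse rank-one trends
sequentially:

    X  ~  d * u v^T,    u = per-gene scores (sparse),  v = trend over bins

by alternating updates — the gene side is a soft-thresholded projection
(L1 penalty, so most gene scores are exactly zero) and the bin side a
second-difference-penalized ridge solve (so trends are smooth curves).
After each accepted rank the fitted component is deflated from X and the
next trend is extracted; three ranks usually capture the main expression
programs along a branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class BranchMatrix:
    """Neighbor-averaged expression along one branch (genes x bins)."""

    values: np.ndarray
    bin_pseudotime: np.ndarray
    gene_ids: list[str]
    branch: str = ""

    def __post_init__(self) -> None:
        scale = max(1.0, float(np.max(np.abs(self.bin_pseudotime), initial=0)))
        if np.any(np.diff(self.bin_pseudotime) < -1e-9 * scale):
            raise ValueError("bin_pseudotime must be nondecreasing")


@dataclass
class RankTrend:
    d: float
    scores: np.ndarray  # per-gene vector u (sparse under L1)
    trend: np.ndarray  # per-bin unit-norm vector v
    varexp: float
    converged: bool = True


@dataclass
class TrendResult:
    ranks: list[RankTrend]
    gene_ids: list[str]
    branch: str = ""

    def to_frame(self) -> pd.DataFrame:
        data = {"rank": [], "gene": [], "score": []}
        for r, rk in enumerate(self.ranks, start=1):
            for g, s in zip(self.gene_ids, rk.scores):
                if s != 0:
                    data["rank"].append(r)
                    data["gene"].append(g)
                    data["score"].append(s)
        return pd.DataFrame(data)


def bin_branch(cells: list[int], expr: ExpressionMatrix,
               pseudotime: np.ndarray, n_bins: int = 0) -> BranchMatrix:
    """Average cells into contiguous equal-count pseudotime bins.

    ``cells`` must already be ordered by pseudotime.  The default bin
    count is min(100, n_cells); when cells cannot fill the requested bins
    the count is reduced with a warning.  Any remainder is spread over the
    leading bins (sizes differ by at most one, larger bins first).
    """
    n = len(cells)
    if n == 0:
        raise ValueError("no cells on branch")
    if n_bins <= 0:
        n_bins = min(100, n)
    if n_bins > n:
        warnings.warn(f"{n} cells < {n_bins} bins; reducing bin count")
        n_bins = n
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    X = expr.dense()
    vals = np.empty((expr.n_features, n_bins))
    bt = np.empty(n_bins)
    start = 0
    for b, s in enumerate(sizes):
        grp = cells[start:start + s]
        vals[:, b] = X[grp].mean(axis=0)
        bt[b] = float(np.mean(pseudotime[grp]))
        start += s
    return BranchMatrix(values=vals, bin_pseudotime=bt,
                        gene_ids=list(expr.feature_ids))


# ---------------------------------------------------------------------------
# rank-one PTA
# ---------------------------------------------------------------------------

def _second_difference(n: int) -> np.ndarray:
    """(n-2) x n second-difference operator."""
    D = np.zeros((max(n - 2, 0), n))
    for i in range(n - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def _soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def smooth_gcv(y: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Pick the second-difference ridge penalty by generalized CV.

    For the smoother S(lam) = (I + lam D2'D2)^-1, GCV(lam) =
    n ||(I - S) y||^2 / tr(I - S)^2; the grid minimizer is returned.
    """
    n = len(y)
    if grid is None:
        grid = np.logspace(-3, 3, 25)
    D = _second_difference(n)
    P = D.T @ D
    best, best_lam = np.inf, float(grid[0])
    for lam in grid:
        S = np.linalg.inv(np.eye(n) + lam * P)
        resid = y - S @ y
        denom = (n - np.trace(S)) ** 2
        if denom <= 0:
            continue
        g = n * float(resid @ resid) / denom
        if g < best:
            best, best_lam = g, float(lam)
    return best_lam


def pta_rank_one(
    X: np.ndarray,
    lambda_sparse: float | None = None,
    lambda_smooth: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> RankTrend:
    """One sparse-smooth rank-one factor of a genes x bins matrix.

    Alternating optimization initialized from the leading singular pair:
    the gene scores u are a soft-thresholded, renormalized projection
    ``S(X v, lambda_sparse)``; the trend v solves the smoothing system
    ``(I + lambda_smooth D2'D2) v = X' u`` and is renormalized; the
    magnitude is ``d = u' X v``.  Convergence when the relative change in
    d drops below ``tol``.  ``lambda_sparse=None`` uses the universal
    soft-threshold sigma * sqrt(2 log g), with sigma the MAD estimate of
    the noise scale of X v, so genes whose projection is consistent with
    noise get exactly zero score; ``lambda_smooth=None`` selects the
    roughness penalty by GCV on the bin axis.

    A saturating sparsity penalty (all scores zeroed) returns a null
    trend with d = 0.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    g, n = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    u, v, d = U[:, 0], Vt[0], float(s[0])
    if d == 0:
        return RankTrend(0.0, np.zeros(g), np.zeros(n), 0.0)

    if lambda_smooth is None:
        lambda_smooth = smooth_gcv(X.T @ u)
    D2 = _second_difference(n)
    M = np.eye(n) + lambda_smooth * (D2.T @ D2)
    M_chol = np.linalg.cholesky(M)

    converged = False
    for _ in range(max_iter):
        z = X @ v
        if lambda_sparse is None:
            # universal threshold with MAD noise estimate
            sigma = float(np.median(np.abs(z - np.median(z)))) / 0.6745
            lam_u = sigma * np.sqrt(2.0 * np.log(max(g, 2)))
        else:
            lam_u = lambda_sparse
        u_new = _soft_threshold(z, lam_u)
        norm_u = np.linalg.norm(u_new)
        if norm_u == 0:
            return RankTrend(0.0, np.zeros(g), np.zeros(n), 0.0)
        u = u_new / norm_u
        rhs = X.T @ u
        v_new = np.linalg.solve(M_chol.T, np.linalg.solve(M_chol, rhs))
        norm_v = np.linalg.norm(v_new)
        if norm_v == 0:
            return RankTrend(0.0, np.zeros(g), np.zeros(n), 0.0)
        v = v_new / norm_v
        d_new = float(u @ X @ v)
        if abs(d_new - d) <= tol * max(abs(d), 1e-12):
            d = d_new
            converged = True
            break
        d = d_new

    # sign convention: trend rises overall (positive endpoint difference)
    if v[-1] - v[0] < 0:
        v, u = -v, -u
    frob2 = float(np.sum(X ** 2))
    resid = X - d * np.outer(u, v)
    varexp = 1.0 - float(np.sum(resid ** 2)) / frob2 if frob2 > 0 else 0.0
    return RankTrend(d=d, scores=u, trend=v, varexp=varexp, converged=converged)


def pta(
    X: BranchMatrix,
    n_ranks: int = 3,
    lambda_sparse: float | None = None,
    lambda_smooth: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> TrendResult:
    """Sequential rank-1..n trend extraction with deflation.

    After each accepted rank the fitted component d u v' is subtracted
    from the working matrix; varexp of rank k is its own share of the
    original squared Frobenius norm.  Three ranks are the conventional
    default for capturing the main expression patterns along a branch.
    """
    if n_ranks < 1:
        raise ValueError("n_ranks must be >= 1")
    work = np.asarray(X.values, dtype=float).copy()
    frob2 = float(np.sum(work ** 2))
    ranks: list[RankTrend] = []
    explained = 0.0
    for _ in range(n_ranks):
        rk = pta_rank_one(work, lambda_sparse=lambda_sparse,
                          lambda_smooth=lambda_smooth,
                          max_iter=max_iter, tol=tol)
        if rk.d == 0:
            ranks.append(rk)
            continue
        work = work - rk.d * np.outer(rk.scores, rk.trend)
        total = 1.0 - float(np.sum(work ** 2)) / frob2 if frob2 > 0 else 0.0
        rk.varexp = total - explained
        explained = total
        ranks.append(rk)
    return TrendResult(ranks=ranks, gene_ids=list(X.gene_ids), branch=X.branch)


def rank_genes(result: TrendResult, rank: int) -> list[tuple[str, float]]:
    """Nonzero-score genes of one rank, ascending by score.

    The ordering (most negative first, most positive last) is the row
    order used for branch heatmaps.
    """
    if not 1 <= rank <= len(result.ranks):
        raise ValueError(f"rank {rank} out of range 1..{len(result.ranks)}")
    scores = result.ranks[rank - 1].scores
    pairs = [(g, float(s)) for g, s in zip(result.gene_ids, scores) if s != 0]
    return sorted(pairs, key=lambda p: p[1])
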