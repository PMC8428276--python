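"""Expression-matrix I/O and preprocessing.

Matrices are held cells x features regardless of the on-disk orientation
(MatrixMarket single-cell convention is genes x cells and is transposed on
load). Preprocessing follows the usual single-cell recipe: filter low-quality
cells, filter low-support features, library-size normalize + log1p, select
highly variable genes, z-scale, PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

Layer = Literal["counts", "lognorm", "scaled", "zscore"]


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix is malformed or inconsistent."""


@dataclass
class ExpressionMatrix:
    """Cells x features matrix with identifiers and a layer tag.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    cells, columns are features.  ``layer`` records the processing state:
    raw ``counts``, library-normalized log1p values (``lognorm``), per-feature
    standardized values (``scaled``), or externally computed ``zscore``
    matrices (e.g. accessibility deviation z-scores) that bypass
    normalization and feed PCA directly.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    feature_ids: list[str]
    layer: Layer = "counts"

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise MatrixFormatError(
                f"values has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise MatrixFormatError(
                f"values has {m} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixFormatError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise MatrixFormatError("duplicate feature ids")
        if self.layer == "counts":
            mn = self.values.min() if sp.issparse(self.values) else np.min(self.values)
            if mn < 0:
                raise MatrixFormatError("counts layer contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (optional convenience)."""
        import anndata

        ad = anndata.AnnData(
            X=self.values,
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.feature_ids),
        )
        ad.uns["layer"] = self.layer
        return ad


@dataclass
class PCSpace:
    """PCA coordinates together with the scree information.

    ``coords`` is cells x n_components; ``explained_variance`` holds the
    per-component fraction of total variance (nonincreasing); ``n_selected``
    is the number of leading components retained for downstream steps.
    """

    coords: np.ndarray
    explained_variance: np.ndarray
    n_selected: int = field(default=0)

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be nonincreasing")
        if self.n_selected == 0:
            self.n_selected = self.coords.shape[1]
        if not 1 <= self.n_selected <= self.coords.shape[1]:
            raise ValueError("n_selected out of range")

    @property
    def selected(self) -> np.ndarray:
        """Coordinates restricted to the retained leading components."""
        return self.coords[:, : self.n_selected]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_ids(path: Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def load_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from MTX triplet, dense CSV/TSV, or HDF5.

    MTX follows the single-cell convention genes x cells on disk with
    ``barcodes.tsv`` / ``features.tsv`` sidecars next to the matrix file,
    and is transposed to cells x features on load.  CSV/TSV is cells x
    features with a header row of feature ids and the first column holding
    cell ids.  HDF5 stores ``/X`` (cells x features), ``/obs/ids`` and
    ``/var/ids``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv",
                  ".h5": "h5", ".hdf5": "h5"}.get(suffix)
        if format is None:
            raise MatrixFormatError(f"cannot infer format from {path.name}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        try:
            m = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise MatrixFormatError(f"malformed MTX file {path}: {exc}") from exc
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        if not barcodes.exists() or not features.exists():
            raise MatrixFormatError(
                f"MTX sidecars barcodes.tsv/features.tsv not found next to {path}"
            )
        cell_ids = _read_ids(barcodes)
        feature_ids = _read_ids(features)
        mat = sp.csr_matrix(m).T  # genes x cells on disk
        if mat.shape != (len(cell_ids), len(feature_ids)):
            raise MatrixFormatError(
                f"MTX is {m.shape} (genes x cells) but sidecars give "
                f"{len(feature_ids)} features / {len(cell_ids)} cells"
            )
        return ExpressionMatrix(mat, cell_ids, feature_ids)

    if format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        except pd.errors.ParserError as exc:
            raise MatrixFormatError(f"malformed CSV file {path}: {exc}") from exc
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
        )

    if format == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            X = np.asarray(f["X"])
            cell_ids = [x.decode() if isinstance(x, bytes) else str(x)
                        for x in f["obs/ids"][:]]
            feature_ids = [x.decode() if isinstance(x, bytes) else str(x)
                           for x in f["var/ids"][:]]
            layer = f.attrs.get("layer", "counts")
        return ExpressionMatrix(X, cell_ids, feature_ids, layer=str(layer))

    raise MatrixFormatError(f"unknown format {format!r}")


def save_matrix(mat: ExpressionMatrix, path: str | Path,
                format: str | None = None) -> None:
    """Write a matrix in any of the formats :func:`load_matrix` reads."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv",
                  ".h5": "h5", ".hdf5": "h5"}.get(suffix, "csv")
    path.parent.mkdir(parents=True, exist_ok=True)

    if format == "mtx":
        coo = sp.coo_matrix(mat.values).T  # store genes x cells
        scipy.io.mmwrite(str(path), coo)
        pd.Series(mat.cell_ids).to_csv(path.parent / "barcodes.tsv",
                                       sep="\t", index=False, header=False)
        pd.Series(mat.feature_ids).to_csv(path.parent / "features.tsv",
                                          sep="\t", index=False, header=False)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pd.DataFrame(mat.dense(), index=mat.cell_ids,
                     columns=mat.feature_ids).to_csv(path, sep=sep)
    elif format == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=mat.dense())
            f.create_dataset("obs/ids",
                             data=np.array(mat.cell_ids, dtype="S"))
            f.create_dataset("var/ids",
                             data=np.array(mat.feature_ids, dtype="S"))
            f.attrs["layer"] = mat.layer
    else:
        raise MatrixFormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_and_normalize(
    mat: ExpressionMatrix,
    min_features_per_cell: int = 200,
    min_cells_per_feature: int = 3,
    scale_factor: float = 1e4,
) -> ExpressionMatrix:
    """Filter low-quality cells then low-support features; normalize + log1p.

    Cells with fewer than ``min_features_per_cell`` detected (nonzero)
    features are removed first; features detected in fewer than
    ``min_cells_per_feature`` of the surviving cells are removed second.
    Remaining counts are scaled so every cell sums to ``scale_factor`` and
    log1p-transformed; the result carries layer ``lognorm``.
    """
    if mat.layer != "counts":
        raise ValueError(f"expected counts layer, got {mat.layer}")
    X = mat.dense()
    cell_keep = (X > 0).sum(axis=1) >= min_features_per_cell
    if not cell_keep.any():
        raise ValueError("all cells removed by filtering")
    X = X[cell_keep]
    feat_keep = (X > 0).sum(axis=0) >= min_cells_per_feature
    X = X[:, feat_keep]
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(X / totals * scale_factor)
    return ExpressionMatrix(
        X,
        [c for c, k in zip(mat.cell_ids, cell_keep) if k],
        [f for f, k in zip(mat.feature_ids, feat_keep) if k],
        layer="lognorm",
    )


def hvg_dispersion(X: np.ndarray) -> np.ndarray:
    """Variance-stabilized dispersion: residual of log-variance on log-mean.

    A quadratic trend of log variance against log mean is fitted across
    features; the residual ranks features by variance in excess of what
    their expression level predicts.  Deterministic given the input.
    """
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    lm = np.log1p(mean)
    lv = np.log1p(var)
    if np.allclose(lm, lm[0]):
        res = lv - lv.mean()
    else:
        coef = np.polyfit(lm, lv, deg=min(2, len(np.unique(lm)) - 1))
        res = lv - np.polyval(coef, lm)
    res[var == 0] = -np.inf  # constant features are never variable
    return res


def select_hvg(mat: ExpressionMatrix, n_top: int = 2000) -> list[str]:
    """Select the ``n_top`` most variable features of a lognorm matrix."""
    if mat.layer != "lognorm":
        raise ValueError(f"expected lognorm layer, got {mat.layer}")
    if n_top > mat.n_features:
        warnings.warn(
            f"n_top={n_top} exceeds feature count {mat.n_features}; clamping"
        )
        n_top = mat.n_features
    disp = hvg_dispersion(mat.dense())
    # stable: sort by (-dispersion, index) so ties resolve to earlier features
    order = np.lexsort((np.arange(len(disp)), -disp))
    return [mat.feature_ids[i] for i in sorted(order[:n_top])]


def subset_features(mat: ExpressionMatrix, feature_ids: Sequence[str]) -> ExpressionMatrix:
    """Restrict a matrix to the given features (kept in matrix order)."""
    keep = set(feature_ids)
    idx = [i for i, f in enumerate(mat.feature_ids) if f in keep]
    return replace(
        mat,
        values=mat.dense()[:, idx],
        feature_ids=[mat.feature_ids[i] for i in idx],
    )


def scale_features(mat: ExpressionMatrix, clip: float = 10.0) -> ExpressionMatrix:
    """Center each feature to mean 0 / unit variance and clip to ``±clip``.

    Zero-variance features become all-zero columns.  Uses the unbiased
    (ddof=1) standard deviation, matching common single-cell toolkits.
    """
    if mat.layer != "lognorm":
        raise ValueError(f"expected lognorm layer, got {mat.layer}")
    X = mat.dense()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    sd = np.where(sd == 0, 1.0, sd)
    Z = np.clip((X - mu) / sd, -clip, clip)
    return replace(mat, values=Z, layer="scaled")


def run_pca(mat: ExpressionMatrix, n_components: int = 50,
            seed: int = 0) -> PCSpace:
    """PCA of a scaled (or z-score) matrix with a fixed sign convention.

    Components are projections onto the top right-singular directions of
    the centered matrix.  For reproducibility each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    if mat.layer not in ("scaled", "zscore"):
        raise ValueError(f"expected scaled or zscore layer, got {mat.layer}")
    X = mat.dense()
    max_rank = min(X.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; reducing"
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    return PCSpace(coords=coords,
                   explained_variance=pca.explained_variance_ratio_.copy())


def select_components(pcs: PCSpace, method: str = "elbow",
                      cumvar_target: float = 0.9) -> int:
    """Choose how many leading components to keep.

    ``elbow`` takes the scree point with maximum perpendicular distance to
    the chord joining the first and last points; ``cumvar`` takes the
    smallest k whose cumulative explained-variance fraction reaches
    ``cumvar_target``.  The choice is advisory; callers may override.
    """
    ev = np.asarray(pcs.explained_variance, dtype=float)
    if len(ev) < 2:
        return len(ev)
    if method == "cumvar":
        cum = np.cumsum(ev)
        hit = np.nonzero(cum >= cumvar_target - 1e-12)[0]
        return int(hit[0]) + 1 if len(hit) else len(ev)
    if method == "elbow":
        n = len(ev)
        x = np.arange(n, dtype=float)
        p0 = np.array([x[0], ev[0]])
        p1 = np.array([x[-1], ev[-1]])
        chord = p1 - p0
        chord /= np.linalg.norm(chord)
        rel = np.stack([x, ev], axis=1) - p0
        # perpendicular distance of each scree point to the chord
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        return int(np.argmax(dist)) + 1
    raise ValueError(f"unknown method {method!r}")
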