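import numpy as np
import pytest
import scipy.io
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from treetrace.matrix import (ExpressionMatrix, MatrixFormatError, PCSpace,
                              filter_and_normalize, hvg_dispersion,
                              load_matrix, run_pca, save_matrix,
                              scale_features, select_components, select_hvg)


class TestIO:
    @pytest.mark.parametrize("fmt,fname", [
        ("csv", "m.csv"), ("mtx", "m.mtx"), ("h5", "m.h5"),
    ])
    def test_round_trip_value_identity(self, tmp_path, counts_matrix, fmt, fname):
        save_matrix(counts_matrix, tmp_path / fname, fmt)
        back = load_matrix(tmp_path / fname, fmt)
        np.testing.assert_allclose(back.dense(), counts_matrix.dense())
        assert back.cell_ids == counts_matrix.cell_ids
        assert back.feature_ids == counts_matrix.feature_ids

    def test_csv_orientation(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "cell,gA,gB\nc1,1,2\nc2,3,4\nc3,5,6\n")
        m = load_matrix(tmp_path / "m.csv")
        assert m.n_cells == 3 and m.n_features == 2
        assert m.cell_ids == ["c1", "c2", "c3"]

    def test_mtx_triplet_replay(self, tmp_path):
        # 5 nonzeros among 4 cells x 3 genes; on disk genes x cells
        triplets = [(0, 0, 2.0), (1, 1, 3.0), (2, 2, 1.0), (0, 3, 5.0),
                    (2, 0, 4.0)]  # (gene, cell, value)
        genes, cells, vals = zip(*triplets)
        coo = sp.coo_matrix((vals, (genes, cells)), shape=(3, 4))
        scipy.io.mmwrite(str(tmp_path / "m.mtx"), coo)
        (tmp_path / "barcodes.tsv").write_text("c0\nc1\nc2\nc3\n")
        (tmp_path / "features.tsv").write_text("g0\ng1\ng2\n")
        m = load_matrix(tmp_path / "m.mtx")
        # oracle: place every triplet into a dense cells x genes array
        expected = np.zeros((4, 3))
        for g, c, v in triplets:
            expected[c, g] = v
        np.testing.assert_allclose(m.dense(), expected)

    def test_mtx_sidecar_mismatch_raises(self, tmp_path):
        coo = sp.coo_matrix(np.ones((3, 4)))
        scipy.io.mmwrite(str(tmp_path / "m.mtx"), coo)
        (tmp_path / "barcodes.tsv").write_text("c0\nc1\n")  # wrong count
        (tmp_path / "features.tsv").write_text("g0\ng1\ng2\n")
        with pytest.raises(MatrixFormatError):
            load_matrix(tmp_path / "m.mtx")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(MatrixFormatError):
            ExpressionMatrix(np.ones((2, 1)), ["a", "a"], ["g"])


class TestFilterNormalize:
    def test_zero_thresholds_only_normalize(self, counts_matrix):
        out = filter_and_normalize(counts_matrix, 0, 0, scale_factor=100)
        assert out.cell_ids == counts_matrix.cell_ids
        assert out.feature_ids == counts_matrix.feature_ids
        assert out.layer == "lognorm"

    def test_normalization_closed_form(self):
        m = ExpressionMatrix(np.array([[3.0, 7.0]]), ["c"], ["g1", "g2"])
        out = filter_and_normalize(m, 0, 0, scale_factor=50)
        assert out.values[0, 0] == pytest.approx(np.log1p(3 * 50 / 10))

    def test_cell_filter_matches_row_scan(self, rng):
        X = rng.poisson(0.8, size=(6, 4)).astype(float)
        m = ExpressionMatrix(X, [f"c{i}" for i in range(6)],
                             [f"g{j}" for j in range(4)])
        out = filter_and_normalize(m, min_features_per_cell=2,
                                   min_cells_per_feature=0)
        survivors = [f"c{i}" for i in range(6) if (X[i] > 0).sum() >= 2]
        assert out.cell_ids == survivors

    def test_all_cells_removed_raises(self, counts_matrix):
        with pytest.raises(ValueError, match="all cells"):
            filter_and_normalize(counts_matrix, 10**6, 0)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.int64, (7, 5), elements=st.integers(0, 4)))
    def test_filter_order_cells_then_features(self, X):
        """Filtering equals a two-pass scan: cells first, then features."""
        Xf = X.astype(float)
        m = ExpressionMatrix(Xf, [f"c{i}" for i in range(7)],
                             [f"g{j}" for j in range(5)])
        cell_keep = [(Xf[i] > 0).sum() >= 2 for i in range(7)]
        if not any(cell_keep):
            with pytest.raises(ValueError):
                filter_and_normalize(m, 2, 2)
            return
        sub = Xf[np.array(cell_keep)]
        feat_keep = [(sub[:, j] > 0).sum() >= 2 for j in range(5)]
        out = filter_and_normalize(m, 2, 2)
        assert out.cell_ids == [c for c, k in zip(m.cell_ids, cell_keep) if k]
        assert out.feature_ids == [g for g, k in zip(m.feature_ids, feat_keep) if k]


class TestHVG:
    def _lognorm(self, X):
        return ExpressionMatrix(X, [f"c{i}" for i in range(X.shape[0])],
                                [f"g{j}" for j in range(X.shape[1])],
                                layer="lognorm")

    def test_constant_feature_never_selected(self, rng):
        X = rng.normal(2, 1, size=(30, 5)) ** 2
        X[:, 2] = 1.0
        hvg = select_hvg(self._lognorm(X), 4)
        assert "g2" not in hvg

    def test_full_set_returned(self, rng):
        X = rng.random((10, 6))
        assert len(select_hvg(self._lognorm(X), 6)) == 6

    def test_clamped_with_warning(self, rng):
        X = rng.random((10, 6))
        with pytest.warns(UserWarning, match="clamp"):
            hvg = select_hvg(self._lognorm(X), 10)
        assert len(hvg) == 6

    def test_matches_full_sort_oracle(self, rng):
        X = rng.gamma(2.0, 1.0, size=(40, 20))
        m = self._lognorm(X)
        got = set(select_hvg(m, 5))
        disp = hvg_dispersion(X)
        oracle = {m.feature_ids[i] for i in np.argsort(-disp)[:5]}
        assert got == oracle


class TestScale:
    def _lognorm(self, X):
        return ExpressionMatrix(
            np.asarray(X, dtype=float),
            [f"c{i}" for i in range(np.shape(X)[0])],
            [f"g{j}" for j in range(np.shape(X)[1])], layer="lognorm")

    def test_unit_variance_closed_form(self):
        out = scale_features(self._lognorm([[1], [2], [3]]), clip=10)
        np.testing.assert_allclose(out.values.ravel(), [-1, 0, 1])

    def test_clipping(self):
        out = scale_features(self._lognorm([[1], [2], [3]]), clip=0.5)
        np.testing.assert_allclose(out.values.ravel(), [-0.5, 0, 0.5])

    def test_moments(self, rng):
        X = rng.normal(5, 2, size=(30, 8))
        out = scale_features(self._lognorm(X), clip=100)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1,
                                   atol=1e-8)

    def test_zero_variance_maps_to_zeros(self):
        out = scale_features(self._lognorm([[2, 1], [2, 3]]), clip=10)
        np.testing.assert_allclose(out.values[:, 0], 0)


class TestPCA:
    def _scaled(self, X):
        return ExpressionMatrix(
            np.asarray(X, dtype=float),
            [f"c{i}" for i in range(np.shape(X)[0])],
            [f"g{j}" for j in range(np.shape(X)[1])], layer="scaled")

    def test_rank_one_data(self, rng):
        t = rng.normal(size=50)
        direction = rng.normal(size=5)
        X = np.outer(t, direction)
        pcs = run_pca(self._scaled(X), 3)
        assert pcs.explained_variance[0] >= 0.999

    def test_component_orthogonality(self, rng):
        X = rng.normal(size=(40, 10))
        pcs = run_pca(self._scaled(X), 5)
        G = pcs.coords.T @ pcs.coords
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_variance_matches_covariance_eig(self, rng):
        X = rng.normal(size=(40, 10))
        pcs = run_pca(self._scaled(X), 10)
        C = np.cov((X - X.mean(0)).T)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(pcs.explained_variance,
                                   evals / evals.sum(), atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(20, 6))
        m = self._scaled(X)
        from sklearn.decomposition import PCA

        p = PCA(n_components=6, svd_solver="full").fit(X)
        rec = p.inverse_transform(p.transform(X))
        rel = np.linalg.norm(rec - X) / np.linalg.norm(X)
        assert rel <= 1e-6

    def test_sign_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        a = run_pca(self._scaled(X), 4)
        b = run_pca(self._scaled(X.copy()), 4)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSelectComponents:
    def _pcs(self, ev):
        ev = np.asarray(ev, dtype=float)
        return PCSpace(coords=np.zeros((5, len(ev))), explained_variance=ev)

    def test_cumvar_forced(self):
        assert select_components(self._pcs([0.5, 0.5]), "cumvar", 0.9) == 2

    def test_cumvar_geometric(self):
        ev = 0.5 ** np.arange(1, 9)
        assert select_components(self._pcs(ev / ev.sum() * 0.999999),
                                 "cumvar", 0.7) == 2

    def test_elbow_matches_chord_oracle(self):
        scree = np.array([10, 8, 2, 1.5, 1.4, 1.3])
        ev = scree / scree.sum()
        got = select_components(self._pcs(ev), "elbow")
        # brute force: perpendicular distance of each point to the chord
        x = np.arange(len(ev), dtype=float)
        p0, p1 = np.array([x[0], ev[0]]), np.array([x[-1], ev[-1]])
        best, best_d = 0, -1.0
        for i in range(len(ev)):
            p = np.array([x[i], ev[i]])
            d = abs(np.cross(p1 - p0, p - p0)) / np.linalg.norm(p1 - p0)
            if d > best_d:
                best, best_d = i, d
        assert got == best + 1
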