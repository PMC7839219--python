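import numpy as np
import pandas as pd
import pytest

from scope2 import structure
from scope2.data_model import QuantMatrix


def random_weight_matrix(rng, n):
    A = rng.uniform(0.1, 2.0, (n, n))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestLaplacian:
    def test_quadratic_form_identity(self):
        """v'Lv = 1/2 sum_ij w_ij (v_i - v_j)^2 for random graphs and unit v."""
        rng = np.random.default_rng(0)
        for n in (3, 10, 40):
            W = random_weight_matrix(rng, n)
            L = structure.laplacian(W)
            v = rng.normal(0, 1, n)
            v /= np.linalg.norm(v)
            lhs = v @ L @ v
            rhs = 0.5 * np.sum(W * (v[:, None] - v[None, :]) ** 2)
            assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_smallest_eigenpair_is_zero_constant(self):
        rng = np.random.default_rng(1)
        W = random_weight_matrix(rng, 20)
        evals, evecs = np.linalg.eigh(structure.laplacian(W))
        assert evals[0] == pytest.approx(0.0, abs=1e-9)
        v0 = evecs[:, 0]
        assert np.allclose(v0, v0[0], atol=1e-8)


def two_block_matrix(n_per_block, within=2.0, between=1.0, seed=0):
    """Cell matrix whose correlation graph has the two-block closed form."""
    n = 2 * n_per_block
    W = np.full((n, n), between)
    W[:n_per_block, :n_per_block] = within
    W[n_per_block:, n_per_block:] = within
    return W


class TestFiedler:
    def test_two_block_closed_form(self):
        """Within-weight a, between-weight b, equal blocks of n: the Fiedler
        eigenvalue is 2nb and the vector is the block indicator."""
        n = 4
        W = two_block_matrix(n, within=2.0, between=1.0)
        L = structure.laplacian(W)
        evals, evecs = np.linalg.eigh(L)
        assert evals[1] == pytest.approx(2 * n * 1.0, abs=1e-9)
        v = evecs[:, 1]
        assert np.allclose(np.abs(v), 1 / np.sqrt(2 * n), atol=1e-9)
        assert np.sign(v[0]) != np.sign(v[-1])
        assert np.allclose(v[:n], v[0]) and np.allclose(v[n:], v[-1])

    def test_block_data_orders_by_block(self):
        rng = np.random.default_rng(2)
        shift = np.concatenate([np.ones(5), -np.ones(5)])
        X = rng.normal(0, 0.1, (30, 10)) + np.outer(rng.choice([1, -1], 30), shift)
        m = QuantMatrix(
            pd.DataFrame(X, columns=[f"c{i:02d}" for i in range(10)]),
            level="protein",
            state="batch_corrected",
        )
        res = structure.fiedler_order(m)
        signs = np.sign(res.fiedler.to_numpy())
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[-1]
        clusters = structure.spectral_clusters(res)
        assert clusters.nunique() == 2

    def test_fiedler_orthogonal_to_constant_and_unit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 8))
        m = QuantMatrix(pd.DataFrame(X, columns=[f"c{i}" for i in range(8)]),
                        level="protein", state="batch_corrected")
        res = structure.fiedler_order(m)
        v = res.fiedler.to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.dot(v, np.ones_like(v)) == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_graph_falls_back_to_id_order(self):
        # all pairwise correlations equal (duplicated column pattern)
        X = np.outer(np.arange(1, 6), np.ones(4)) + np.outer(np.ones(5), [0, 1, 2, 3])
        m = QuantMatrix(pd.DataFrame(X, columns=["d", "c", "b", "a"]),
                        level="protein", state="batch_corrected")
        with pytest.warns(UserWarning, match="degenerate"):
            res = structure.fiedler_order(m)
        assert res.degenerate
        assert res.ordering == ["a", "b", "c", "d"]

    def test_too_few_cells_rejected(self):
        m = QuantMatrix(pd.DataFrame(np.eye(4)[:, :2], columns=["a", "b"]),
                        level="protein", state="batch_corrected")
        with pytest.raises(ValueError, match="at least 3"):
            structure.fiedler_order(m)


class TestWeightedPca:
    def _two_type_matrix(self, n_prot=60, n_per_type=15, effect=2.0, seed=0):
        rng = np.random.default_rng(seed)
        shift = np.concatenate([np.ones(n_per_type), -np.ones(n_per_type)])
        dirn = rng.choice([1.0, -1.0], n_prot)
        X = 0.5 * rng.normal(size=(n_prot, 2 * n_per_type)) + effect * np.outer(dirn, shift) / 2
        cols = [f"a{i:02d}" for i in range(n_per_type)] + [f"b{i:02d}" for i in range(n_per_type)]
        idx = [f"f{i}" for i in range(n_prot)]
        return QuantMatrix(pd.DataFrame(X, index=idx, columns=cols), level="protein",
                           state="batch_corrected")

    def test_pc1_separates_two_types(self):
        m = self._two_type_matrix()
        res = structure.weighted_pca(m)
        pc1 = res.cell_scores["PC1"].to_numpy()
        assert len(set(np.sign(pc1[:15]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[-1])
        assert res.variance_fraction[0] > 0.5

    def test_variance_fractions_valid_and_permutation_invariant(self):
        m = self._two_type_matrix(seed=4)
        res = structure.weighted_pca(m)
        vf = res.variance_fraction
        assert np.all(vf >= -1e-12) and vf.sum() == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.values.shape[1])
        m2 = QuantMatrix(m.values.iloc[:, perm], level="protein", state="batch_corrected")
        res2 = structure.weighted_pca(m2)
        np.testing.assert_allclose(res2.variance_fraction, vf, atol=1e-9)

    def test_duplicate_cells_get_identical_scores(self):
        m = self._two_type_matrix(seed=5)
        dup = m.values.copy()
        dup["a00_copy"] = dup["a00"]
        res = structure.weighted_pca(
            QuantMatrix(dup, level="protein", state="batch_corrected")
        )
        # compare only informative components; the trailing null-space
        # eigenvectors created by the exact duplication are arbitrary
        informative = res.variance_fraction > 1e-8
        np.testing.assert_allclose(
            res.cell_scores.loc["a00"].to_numpy()[informative],
            res.cell_scores.loc["a00_copy"].to_numpy()[informative],
            atol=1e-9,
        )

    def test_uncorrelated_proteins_approach_unweighted_pca(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (400, 30))
        m = QuantMatrix(pd.DataFrame(X, columns=[f"c{i}" for i in range(30)]),
                        level="protein", state="batch_corrected")
        res = structure.weighted_pca(m)
        w = res.protein_weights.to_numpy()
        # weights concentrate near 1 + (n_cells-ish)/n_prot noise floor
        assert w.std() / w.mean() < 0.15
        plain = np.linalg.eigvalsh(np.corrcoef(X.T))[::-1]
        np.testing.assert_allclose(
            res.variance_fraction[:5], plain[:5] / plain.sum(), rtol=0.15
        )

    def test_zero_variance_protein_dropped(self):
        X = np.vstack([np.ones(6), np.random.default_rng(0).normal(0, 1, (10, 6))])
        m = QuantMatrix(pd.DataFrame(X, columns=[f"c{i}" for i in range(6)]),
                        level="protein", state="batch_corrected")
        with pytest.warns(UserWarning, match="zero-variance"):
            res = structure.weighted_pca(m)
        assert len(res.protein_weights) == 10


class TestTopVariable:
    def _m(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.1, (10, 8))
        X[:5, :4] += np.linspace(1, 5, 5)[:, None]  # f0..f4 differential
        return QuantMatrix(
            pd.DataFrame(X, index=[f"f{i}" for i in range(10)],
                         columns=[f"c{i}" for i in range(8)]),
            level="protein", state="batch_corrected")

    def test_cluster_mode_fraction(self):
        m = self._m()
        labels = pd.Series([1] * 4 + [2] * 4, index=m.values.columns)
        assert len(structure.top_variable_proteins(m, labels, 1.0)) == 10
        top2 = structure.top_variable_proteins(m, labels, 0.2)
        assert top2 == ["f4", "f3"]

    def test_edge_mode(self):
        m = self._m()
        ordered = list(m.values.columns)
        top = structure.top_variable_proteins(m, ordered, 0.5, mode="edges", n_edge=4)
        assert set(top) == {"f0", "f1", "f2", "f3", "f4"}

    def test_truly_differential_proteins_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.3, (50, 40))
        X[:5, :20] += 3.0
        m = QuantMatrix(
            pd.DataFrame(X, index=[f"f{i}" for i in range(50)],
                         columns=[f"c{i}" for i in range(40)]),
            level="protein", state="batch_corrected")
        labels = pd.Series([1] * 20 + [2] * 20, index=m.values.columns)
        top = structure.top_variable_proteins(m, labels, 0.1)
        assert set(top) == {"f0", "f1", "f2", "f3", "f4"}


class TestBulkMarkers:
    def _bulk(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (100, 40))
        X[0, :20] += 5.0  # 5-sigma separated protein
        X[1] = 0.7  # identical across groups
        cols = [f"mono{i}" for i in range(20)] + [f"mac{i}" for i in range(20)]
        labels = pd.Series(["mono"] * 20 + ["mac"] * 20, index=cols)
        idx = [f"f{i}" for i in range(100)]
        return QuantMatrix(pd.DataFrame(X, index=idx, columns=cols), level="protein",
                           state="batch_corrected"), labels

    def test_large_effect_selected_flat_excluded(self):
        bulk, labels = self._bulk()
        res = structure.bulk_markers(bulk, labels, n_per_side=5)
        assert "f0" in res.index and res.loc["f0", "p"] < 0.01
        assert "f1" not in res.index

    def test_too_few_replicates_rejected(self):
        bulk, labels = self._bulk()
        small = labels.iloc[[0, 20]]
        with pytest.raises(ValueError, match="replicates"):
            structure.bulk_markers(
                QuantMatrix(bulk.values[small.index], level="protein",
                            state="batch_corrected"),
                small,
            )

    def test_fewer_than_requested_warns(self):
        bulk, labels = self._bulk()
        with pytest.warns(UserWarning, match="markers pass"):
            res = structure.bulk_markers(bulk, labels, n_per_side=30)
        assert len(res) < 60


class TestGeneSetEnrichment:
    def test_whole_background_set_is_null(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(0, 1, 500), index=[f"g{i}" for i in range(500)])
        res = structure.gene_set_enrichment(values, {"all": list(values.index)})
        assert res.loc["all", "p"] == 1.0

    def test_shifted_set_detected(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(0, 1, 2000), index=[f"g{i}" for i in range(2000)])
        values.iloc[:50] += 2.0
        sets = {"shifted": [f"g{i}" for i in range(50)],
                "random": [f"g{i}" for i in range(1000, 1050)]}
        res = structure.gene_set_enrichment(values, sets)
        assert res.loc["shifted", "p"] < 0.01
        assert res.loc["shifted", "effect"] > res.loc["random", "effect"]
        assert "p_adj" in res.columns

    def test_empty_set_skipped_with_warning(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="no members"):
            res = structure.gene_set_enrichment(values, {"ghost": ["x", "y"]})
        assert len(res) == 0
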