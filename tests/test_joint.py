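import numpy as np
import pandas as pd
import pytest

from scope2 import joint, simulate


def _random_pair(seed=0, n_genes=30, n_cells=50):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    rna = pd.DataFrame(rng.normal(0, 1, (n_genes, n_cells)), index=genes)
    prot = pd.DataFrame(rng.normal(0, 1, (n_genes, n_cells)), index=genes)
    return rna, prot


class TestCorrelationVectors:
    def test_identical_data_gives_rho_one(self):
        rna, _ = _random_pair()
        pairs, _, _ = joint.correlation_vectors(rna, rna.copy())
        assert all(p.rho_rp == pytest.approx(1.0) for p in pairs)

    def test_global_sign_flip_is_invisible(self):
        """Correlation matrices are invariant under negating the data, so
        rho_rp stays +1, not -1."""
        rna, _ = _random_pair(1)
        pairs, _, _ = joint.correlation_vectors(rna, -rna)
        assert all(p.rho_rp == pytest.approx(1.0) for p in pairs)

    def test_independent_data_centered_near_zero(self):
        rna, prot = _random_pair(2, n_genes=60, n_cells=400)
        pairs, _, _ = joint.correlation_vectors(rna, prot)
        rho = np.array([p.rho_rp for p in pairs])
        assert abs(np.mean(rho)) < 0.1

    def test_too_few_shared_genes_rejected(self):
        rna, prot = _random_pair()
        with pytest.raises(ValueError, match="shared genes"):
            joint.correlation_vectors(rna.iloc[:2], prot.iloc[:2])

    def test_invariant_to_shared_cell_permutation(self):
        rna, prot = _random_pair(3)
        pairs, _, _ = joint.correlation_vectors(rna, prot)
        perm = np.random.default_rng(0).permutation(rna.shape[1])
        pairs2, _, _ = joint.correlation_vectors(
            rna.iloc[:, perm], prot.iloc[:, perm]
        )
        np.testing.assert_allclose(
            [p.rho_rp for p in pairs], [p.rho_rp for p in pairs2], atol=1e-12
        )


class TestPermutationNull:
    def test_centered_at_zero_on_structured_data(self):
        rna, prot, _ = simulate.simulate_joint(n_genes=80, n_cells=200, seed=1)
        _, Rr, Rp = joint.correlation_vectors(rna, prot)
        null = joint.permutation_null(Rr, Rp, n_perm=50, seed=0)
        assert abs(np.nanmean(null)) < 0.05

    def test_seed_determinism(self):
        rna, prot = _random_pair(4)
        _, Rr, Rp = joint.correlation_vectors(rna, prot)
        a = joint.permutation_null(Rr, Rp, 5, seed=7)
        b = joint.permutation_null(Rr, Rp, 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_zero_permutations_rejected(self):
        rna, prot = _random_pair()
        _, Rr, Rp = joint.correlation_vectors(rna, prot)
        with pytest.raises(ValueError, match="n_perm"):
            joint.permutation_null(Rr, Rp, 0, seed=0)


class TestGeneClusters:
    def test_bimodal_distribution_split_cleanly(self):
        rna, prot, labels = simulate.simulate_joint(n_genes=150, n_cells=250, seed=5)
        pairs, _, _ = joint.correlation_vectors(rna, prot)
        pairs = joint.define_gene_clusters(pairs)
        pred = pd.Series({p.gene: p.cluster for p in pairs})
        acc = (pred == labels).mean()
        assert acc >= 0.9

    def test_recomputation_within_cluster_raises_agreement(self):
        rna, prot, labels = simulate.simulate_joint(n_genes=150, n_cells=250, seed=6)
        pairs, _, _ = joint.correlation_vectors(rna, prot)
        pairs = joint.define_gene_clusters(pairs)
        c1 = [p.gene for p in pairs if p.cluster == 1]
        within, _, _ = joint.correlation_vectors(rna.loc[c1], prot.loc[c1])
        rho_all = np.mean([p.rho_rp for p in pairs if p.cluster == 1])
        rho_within = np.mean([p.rho_rp for p in within])
        assert rho_within > rho_all

    def test_unimodal_distribution_assigns_none(self):
        rna, prot = _random_pair(8, n_genes=80, n_cells=300)
        pairs, _, _ = joint.correlation_vectors(rna, prot)
        with pytest.warns(UserWarning, match="not bimodal"):
            pairs = joint.define_gene_clusters(pairs)
        assert all(p.cluster is None for p in pairs)

    def test_single_gene_unassigned(self):
        pairs = [joint.CovarPair("g", 0.5)]
        with pytest.warns(UserWarning, match="too few"):
            out = joint.define_gene_clusters(pairs)
        assert out[0].cluster is None


class TestCpca:
    def test_equal_matrices_reduce_to_pca(self):
        rna, _ = _random_pair(9, n_genes=20, n_cells=100)
        _, Rr, _ = joint.correlation_vectors(rna, rna.copy())
        res = joint.cpca(Rr, Rr, rna, rna.copy())
        evals, evecs = np.linalg.eigh(Rr)
        pc1 = evecs[:, -1]
        assert abs(np.dot(res.cpc1.to_numpy(), pc1)) == pytest.approx(1.0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        Rr = np.array([[1.0, 0.8], [0.8, 1.0]])
        Rp = np.array([[1.0, 0.4], [0.4, 1.0]])
        rng = np.random.default_rng(0)
        rna = pd.DataFrame(rng.normal(0, 1, (2, 10)), index=["a", "b"])
        prot = pd.DataFrame(rng.normal(0, 1, (2, 10)), index=["a", "b"])
        res = joint.cpca(Rr, Rp, rna, prot)
        np.testing.assert_allclose(np.abs(res.cpc1.to_numpy()), 1 / np.sqrt(2), atol=1e-12)
        assert res.eigenvalues[0] == pytest.approx(3.2)

    def test_identity_matrices_degenerate(self):
        rna, prot = _random_pair(10, n_genes=4)
        I = np.eye(4)
        with pytest.raises(ValueError, match="degenerate_cpc"):
            joint.cpca(I, I, rna.iloc[:4], prot.iloc[:4])

    def test_unit_norm_and_scores_are_projections(self):
        rna, prot, _ = simulate.simulate_joint(n_genes=40, n_cells=60, seed=11)
        _, Rr, Rp = joint.correlation_vectors(rna, prot)
        res = joint.cpca(Rr, Rp, rna, prot)
        assert np.linalg.norm(res.cpc1) == pytest.approx(1.0)
        np.testing.assert_allclose(
            res.rna_cell_scores.to_numpy(),
            (rna.T @ res.cpc1).to_numpy(),
            atol=1e-12,
        )


class TestPairing:
    def test_identical_scores_identity_pairing(self):
        s = pd.Series([3.0, 1.0, 2.0], index=["x", "y", "z"])
        out = joint.pair_cells_by_rank(s, s.copy())
        assert (out["cell_a"] == out["cell_b"]).all()

    def test_shift_invariance(self):
        s = pd.Series([3.0, 1.0, 2.0], index=["x", "y", "z"])
        out = joint.pair_cells_by_rank(s, s + 100.0)
        assert (out["cell_a"] == out["cell_b"]).all()

    def test_anti_aligned_scores_reoriented(self):
        s = pd.Series([3.0, 1.0, 2.0], index=["x", "y", "z"])
        out = joint.pair_cells_by_rank(s, -s)
        assert (out["cell_a"] == out["cell_b"]).all()

    def test_marginals_preserved_and_lengths_checked(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=10), index=[f"a{i}" for i in range(10)])
        b = pd.Series(rng.normal(size=10), index=[f"b{i}" for i in range(10)])
        out = joint.pair_cells_by_rank(a, b)
        assert sorted(out["cell_a"]) == sorted(a.index)
        assert sorted(out["cell_b"]) == sorted(b.index)
        with pytest.raises(ValueError, match="subsample"):
            joint.pair_cells_by_rank(a, b.iloc[:5])


class TestTfTargets:
    def test_activator_split_detected(self):
        rna, prot, pairing, reg = simulate.simulate_tf_regulon(seed=3)
        res = joint.tf_target_correlations(rna, prot, pairing, reg)
        prot_row = res[res["tf_modality"] == "protein"].iloc[0]
        assert prot_row["p"] < 0.01
        assert prot_row["median_r_activated"] > 0 > prot_row["median_r_repressed"]

    def test_shuffled_pairing_destroys_signal(self):
        rna, prot, pairing, reg = simulate.simulate_tf_regulon(seed=4)
        rng = np.random.default_rng(0)
        shuffled = pairing.copy()
        shuffled["cell_b"] = rng.permutation(shuffled["cell_b"].to_numpy())
        res = joint.tf_target_correlations(rna, prot, shuffled, reg)
        prot_row = res[res["tf_modality"] == "protein"].iloc[0]
        assert abs(prot_row["median_r_activated"]) < 0.15
        assert prot_row["p"] > 0.001

    def test_tf_absent_from_protein_gives_rna_only(self):
        rna, prot, pairing, reg = simulate.simulate_tf_regulon(seed=5)
        res = joint.tf_target_correlations(rna, prot.drop(index="TF1"), pairing, reg)
        assert set(res["tf_modality"]) == {"rna"}

    def test_underpowered_tf_reported_without_p(self):
        rna, prot, pairing, reg = simulate.simulate_tf_regulon(
            n_activated=2, n_repressed=2, seed=6
        )
        res = joint.tf_target_correlations(rna, prot, pairing, reg)
        assert res["underpowered"].all()
        assert res["p"].isna().all()
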