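"""Embedding, SNN pre-clustering and consensus sub-clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from snanno.cluster import consensus_matrix, consensus_subcluster, embed, snn_precluster


class TestEmbed:
    def test_pca_on_rank_one_matrix(self, rng):
        u = rng.normal(size=30)
        x = np.outer(u, np.ones(10))
        coords = embed(x, method="pca", n_components=2)
        var = coords.var(axis=0)
        assert var[0] > 0 and var[1] == pytest.approx(0.0, abs=1e-12)

    def test_tsne_deterministic_under_seed(self, rng):
        x = rng.normal(size=(60, 8))
        c1 = embed(x, method="tsne", perplexity=10, seed=3)
        c2 = embed(x, method="tsne", perplexity=10, seed=3)
        np.testing.assert_array_equal(c1, c2)

    def test_perplexity_bound_enforced(self, rng):
        x = rng.normal(size=(30, 5))
        with pytest.raises(ValueError, match="9.7"):
            embed(x, method="tsne", perplexity=15)

    def test_planted_classes_separate_in_embedding(self, rng):
        a = rng.normal(0, 1, (60, 10))
        b = rng.normal(8, 1, (60, 10))
        coords = embed(np.vstack([a, b]), method="tsne", perplexity=20, seed=0)
        ca, cb = coords[:60], coords[60:]
        between = np.linalg.norm(ca.mean(0) - cb.mean(0))
        within = np.percentile(
            np.linalg.norm(ca - ca.mean(0), axis=1), 95
        )
        assert between > within


class TestSNNPrecluster:
    def test_three_planted_blobs(self, rng):
        pts = np.vstack(
            [rng.normal(c, 0.3, (100, 2)) for c in ((0, 0), (10, 0), (0, 10))]
        )
        labels = snn_precluster(pts, k_snn=30)
        truth = np.repeat([0, 1, 2], 100)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_points_single_community(self):
        pts = np.zeros((10, 2))
        labels = snn_precluster(pts, k_snn=3)
        assert len(np.unique(labels)) == 1

    def test_two_distant_pairs(self):
        pts = np.array([[0, 0], [0, 0.1], [100, 100], [100, 100.1]])
        labels = snn_precluster(pts, k_snn=2)
        assert len(np.unique(labels)) == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError, match="k_snn"):
            snn_precluster(np.zeros((5, 2)), k_snn=5)


class TestConsensusSubcluster:
    def test_forced_split_of_one_blob_scores_below_real_structure(self, rng):
        """Consensus silhouettes separate a spurious split of a single blob
        from genuinely planted programs (stability alone saturates the
        consensus, so the comparison — not an absolute level — is the
        diagnostic)."""
        null_res = consensus_subcluster(rng.normal(size=(60, 15)), k=2, seed=0)
        null_sil = np.mean(list(null_res.silhouette.values()))
        blocks = []
        for c in range(2):
            b = rng.normal(0, 0.5, (30, 15))
            b[:, c * 7 : (c + 1) * 7] += 5.0
            blocks.append(b)
        real_res = consensus_subcluster(np.vstack(blocks), k=2, seed=0)
        real_sil = np.mean(list(real_res.silhouette.values()))
        assert null_sil < real_sil
        assert real_sil > 0.9

    def test_planted_programs_recovered(self, rng):
        blocks = []
        truth = []
        for c in range(4):
            b = rng.normal(0, 0.5, (40, 40))
            b[:, c * 10 : (c + 1) * 10] += 5.0
            blocks.append(b)
            truth += [c] * 40
        res = consensus_subcluster(np.vstack(blocks), k=4, seed=1)
        assert adjusted_rand_score(truth, res.labels) >= 0.8
        assert sum(v <= 0.5 for v in res.silhouette.values()) <= 1

    def test_identical_labelings_give_binary_consensus(self):
        lab = np.array([0, 0, 1, 1, 2])
        cons = consensus_matrix([lab, lab, lab])
        assert set(np.unique(cons)) <= {0.0, 1.0}
        np.testing.assert_allclose(np.diag(cons), 1.0)

    def test_disagreeing_labelings_average(self):
        cons = consensus_matrix([np.array([0, 0, 1]), np.array([0, 1, 1])])
        assert cons[0, 1] == pytest.approx(0.5)
        assert cons[1, 2] == pytest.approx(0.5)

    def test_consensus_matrix_invariants(self, rng):
        x = rng.normal(size=(50, 12))
        res = consensus_subcluster(x, k=3, seed=4)
        c = res.consensus
        assert (c >= 0).all() and (c <= 1).all()
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert all(-1 <= v <= 1 for v in res.silhouette.values())

    def test_permutation_consistency(self, rng):
        a = rng.normal(0, 0.2, (25, 8))
        a[:, :4] += 10.0
        b = rng.normal(0, 0.2, (25, 8))
        b[:, 4:] += 10.0
        x = np.vstack([a, b])
        perm = rng.permutation(50)
        r1 = consensus_subcluster(x, k=2, seed=5)
        r2 = consensus_subcluster(x[perm], k=2, seed=5)
        # the partition must be identical up to relabeling; the consensus
        # matrix agrees up to per-run k-means init randomness
        assert adjusted_rand_score(r1.labels[perm], r2.labels) == 1.0
        np.testing.assert_allclose(
            r1.consensus[np.ix_(perm, perm)], r2.consensus, atol=0.25
        )

    def test_preconditions(self, rng):
        x = rng.normal(size=(14, 5))
        with pytest.raises(ValueError, match="k="):
            consensus_subcluster(x, k=10)
        with pytest.raises(ValueError, match="5k"):
            consensus_subcluster(x, k=3)

    def test_exclude_genes_drops_columns(self, small_cohort):
        adata, truth = small_cohort
        from snanno.normalize import log_normalize
        import numpy as np

        astro = adata[(truth["true_class"] == "Astrocyte").to_numpy()]
        log_expr = log_normalize(astro, np.ones(astro.n_obs))
        res = consensus_subcluster(log_expr, k=2, seed=0, exclude_genes=("GFAP",))
        assert res.labels.shape[0] == astro.n_obs
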