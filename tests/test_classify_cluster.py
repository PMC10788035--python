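import numpy as np
import pytest

from bioisofind import (FingerprintConfig, assign_category, category_histogram,
                        fingerprint_set, pca_embed, run_clustering,
                        silhouette_mean, synthetic_fingerprint_blobs,
                        tanimoto_distance_matrix, tune_clusters)


class TestCategories:
    @pytest.mark.parametrize("smiles,label", [
        ("c1ccncc1", "cycle C+N"),
        ("Oc1ccccc1O", "cycle C+O"),
        ("c1ccccc1", "cycle C"),
        ("[F]", "F"),
        ("[Mg]", "Mg"),
        ("CCO", "acyclic C+O"),
        ("CCCC", "acyclic C"),
        ("C1CC1N(S)P", "cycle other"),  # C,N,S,P not in the vocabulary
        ("NCCS(=O)P", "acyclic other"),
        ("*c1ccncc1", "cycle C+N"),  # attachment wildcards ignored
    ])
    def test_assignments(self, smiles, label):
        assert assign_category(smiles) == label

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            assign_category("c1ccc")

    def test_labels_partition_the_set(self):
        smiles = ["c1ccncc1", "CCO", "[F]", "c1ccccc1", "CC(=O)O", "c1ccoc1"]
        hist = category_histogram(smiles)
        assert sum(hist.values()) == len(smiles)

    def test_custom_vocabulary(self):
        assert assign_category("c1ccncc1", cyclic_sets=[{"C"}]) == "cycle other"


class TestFingerprints:
    def test_duplicates_cleaned_before_fingerprinting(self):
        fps, kept = fingerprint_set(["CCO", "CCO", "", "c1ccccc1"])
        assert kept == ["CCO", "c1ccccc1"]
        assert fps.shape == (2, 2048)

    def test_methane_sets_bits_deterministically(self):
        fps1, _ = fingerprint_set(["C"])
        fps2, _ = fingerprint_set(["C"])
        assert fps1.sum() >= 1
        np.testing.assert_array_equal(fps1, fps2)

    def test_unparseable_rows_dropped(self):
        fps, kept = fingerprint_set(["CCO", "not_smiles"])
        assert kept == ["CCO"]
        assert len(fps) == 1

    def test_bit_count_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            FingerprintConfig(n_bits=1000)


class TestTanimotoMatrix:
    def test_hand_counted_distance(self):
        fps = np.zeros((2, 8), dtype=np.uint8)
        fps[0, [1, 2, 3]] = 1
        fps[1, [2, 3, 4]] = 1
        D = tanimoto_distance_matrix(fps)
        assert D[0, 1] == pytest.approx(0.5)  # intersection 2, union 4

    def test_identical_rows_distance_zero(self):
        fps = np.tile(np.array([1, 0, 1, 1, 0, 0, 0, 1], dtype=np.uint8), (2, 1))
        assert tanimoto_distance_matrix(fps)[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        fps = np.zeros((2, 8), dtype=np.uint8)
        fps[0, :4] = 1
        fps[1, 4:] = 1
        assert tanimoto_distance_matrix(fps)[0, 1] == 1.0

    def test_all_zero_rows_by_convention(self):
        fps = np.zeros((2, 8), dtype=np.uint8)
        assert tanimoto_distance_matrix(fps)[0, 1] == 0.0

    def test_symmetric_zero_diagonal_bounded(self):
        fps, _ = synthetic_fingerprint_blobs(3, n_points=30, seed=1)
        D = tanimoto_distance_matrix(fps)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0


def brute_force_silhouette(D, labels):
    """Direct evaluation of s(i) = (b - a) / max(a, b); singletons -> 0."""
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    values = []
    for i in range(len(labels)):
        same = np.flatnonzero((labels == labels[i]) & (np.arange(len(labels)) != i))
        if len(same) == 0:
            values.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == other].mean()
                for other in set(labels.tolist()) if other != labels[i])
        values.append((b - a) / max(a, b))
    return float(np.mean(values))


class TestSilhouette:
    def test_two_tight_pairs_hand_value(self):
        x = np.array([0.0, 0.1, 10.0, 10.1])
        D = np.abs(x[:, None] - x[None, :])
        labels = np.array([0, 0, 1, 1])
        # per point: a = 0.1, b = (10 + 10.1)/2 = 10.05 (or 9.95 side)
        expected = brute_force_silhouette(D, labels)
        assert expected == pytest.approx(0.990, abs=1e-3)
        assert silhouette_mean(D, labels) == pytest.approx(expected, abs=1e-12)

    def test_duplicated_points_score_one(self):
        D = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]],
                     float)
        assert silhouette_mean(D, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = rng.integers(0, 2, size=40)
        s = silhouette_mean(D, labels)
        assert abs(s) < 0.15
        assert s == pytest.approx(brute_force_silhouette(D, labels), abs=1e-12)

    def test_single_cluster_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            silhouette_mean(D, np.zeros(3, dtype=int))

    def test_agrees_with_brute_force_on_small_datasets(self):
        rng = np.random.default_rng(123)
        for n in range(4, 13):
            pts = rng.uniform(size=(n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            for _ in range(5):
                labels = rng.integers(0, 3, size=n)
                if len(set(labels.tolist())) < 2:
                    continue
                assert silhouette_mean(D, labels) == pytest.approx(
                    brute_force_silhouette(D, labels), abs=1e-10)


def _planted_agreement(labels, truth):
    """Fraction of pairs on which two labelings agree (permutation-safe)."""
    same_a = labels[:, None] == labels[None, :]
    same_b = truth[:, None] == truth[None, :]
    return (same_a == same_b).mean()


class TestRunClustering:
    def test_kmeans_recovers_two_blobs(self):
        fps, truth = synthetic_fingerprint_blobs(2, n_points=40, seed=5)
        report = run_clustering(fps, "kmeans", {"k": 2}, seed=0)
        assert report.k == 2
        assert _planted_agreement(report.labels, truth) == 1.0

    def test_kmeans_k_equals_n_zero_sse(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=8, seed=2)
        report = run_clustering(fps, "kmeans", {"k": 8}, seed=0)
        assert report.sse == pytest.approx(0.0, abs=1e-9)

    def test_meanshift_huge_bandwidth_one_cluster(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=20, seed=3)
        report = run_clustering(fps, "meanshift", {"bandwidth": 500.0})
        assert report.k == 1

    def test_k_larger_than_n_rejected(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=6, seed=1)
        with pytest.raises(ValueError):
            run_clustering(fps, "kmeans", {"k": 10})

    def test_unknown_algorithm_rejected(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=6, seed=1)
        with pytest.raises(ValueError):
            run_clustering(fps, "voronoi")

    def test_seeded_runs_reproducible(self):
        fps, _ = synthetic_fingerprint_blobs(3, n_points=30, seed=4)
        a = run_clustering(fps, "kmeans", {"k": 3}, seed=11)
        b = run_clustering(fps, "kmeans", {"k": 3}, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestTuneClusters:
    def test_five_planted_blobs_recovered(self):
        fps, _ = synthetic_fingerprint_blobs(5, n_points=100, seed=7)
        best, report, curves = tune_clusters(fps, "kmeans",
                                             {"k": range(2, 11)}, seed=0)
        assert best["k"] == 5
        assert report.k == 5
        assert len(curves["sse"]) == len(curves["k"]) == 9

    def test_two_planted_blobs_recovered(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=60, seed=9)
        best, _, _ = tune_clusters(fps, "kmeans", {"k": range(2, 8)}, seed=0)
        assert best["k"] == 2

    def test_degeneracy_rule_rejects_k2_when_sse_large(self):
        # 4 well-separated blobs: silhouette at k=2 merges pairs, SSE stays
        # high relative to the single-cluster SSE only when structure remains
        fps, _ = synthetic_fingerprint_blobs(4, n_points=80, seed=13)
        best, _, curves = tune_clusters(fps, "kmeans", {"k": range(2, 9)},
                                        seed=0)
        assert best["k"] == 4

    def test_bandwidth_style_search(self):
        fps, truth = synthetic_fingerprint_blobs(3, n_points=45, seed=6)
        best, report, curves = tune_clusters(
            fps, "meanshift", {"values": [4.0, 8.0, 12.0, 500.0]}, seed=0)
        assert report.k >= 2
        assert len(curves["silhouette"]) == 4

    def test_empty_search_space_rejected(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=10, seed=1)
        with pytest.raises(ValueError):
            tune_clusters(fps, "kmeans", {"k": []})


class TestPCA:
    def test_planar_data_preserves_distances(self):
        rng = np.random.default_rng(2)
        plane = rng.normal(size=(20, 2))
        basis = np.zeros((2, 2048))
        basis[0, 0] = 1.0
        basis[1, 5] = 1.0
        X = plane @ basis
        emb = pca_embed(X, 2)
        D_orig = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        D_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        np.testing.assert_allclose(D_emb, D_orig, atol=1e-6)

    def test_duplicates_map_identically(self):
        fps, _ = synthetic_fingerprint_blobs(2, n_points=10, seed=3)
        X = np.vstack([fps, fps[0]])
        emb = pca_embed(X, 2)
        np.testing.assert_allclose(emb[0], emb[-1], atol=1e-8)

    def test_component_variances_ordered(self):
        fps, _ = synthetic_fingerprint_blobs(4, n_points=40, seed=5)
        emb = pca_embed(fps, 3)
        var = emb.var(axis=0)
        assert var[0] >= var[1] >= var[2]

    def test_deterministic_including_sign(self):
        fps, _ = synthetic_fingerprint_blobs(3, n_points=30, seed=6)
        np.testing.assert_allclose(pca_embed(fps, 2), pca_embed(fps, 2))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(np.zeros((2, 16)), 2)
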