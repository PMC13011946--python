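"""Consensus-clustering correctness: brute-force k-means oracles,
centroid-matrix geometry, label-permutation invariance, and
independent-formula validity metrics."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import lbpstrat as L
from lbpstrat.consensus import CentroidMatrix, canonicalize_labels


def wcss(points, labels):
    total = 0.0
    for lab in np.unique(labels):
        cluster = points[labels == lab]
        total += ((cluster - cluster.mean(axis=0)) ** 2).sum()
    return total


def brute_force_min_wcss(points, k):
    """Exhaustive minimum within-cluster sum of squares over all
    assignments of n points to k (non-empty) groups."""
    n = len(points)
    best, best_labels = np.inf, None
    for assignment in itertools.product(range(k), repeat=n):
        labels = np.array(assignment)
        if len(np.unique(labels)) < k:
            continue
        w = wcss(points, labels)
        if w < best - 1e-12:
            best, best_labels = w, labels
    return best, best_labels


def partitions_equal(a, b):
    return adjusted_rand_score(a, b) == pytest.approx(1.0)


def test_kmeans_two_blob_partition_matches_brute_force():
    points = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    _, labels = L.kmeans_fit(points, 2, seed=0)
    _, oracle = brute_force_min_wcss(points, 2)
    assert partitions_equal(labels, oracle)


def test_kmeans_k1_and_kn_limits():
    rng = np.random.default_rng(3)
    points = rng.normal(size=(6, 2))
    centroids, labels = L.kmeans_fit(points, 1, seed=0)
    np.testing.assert_allclose(centroids[0], points.mean(axis=0))
    _, labels_n = L.kmeans_fit(points, 6, seed=0)
    assert wcss(points, labels_n) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        L.kmeans_fit(points, 7, seed=0)


@pytest.mark.parametrize("n, k, seed", [(8, 2, 0), (10, 3, 1), (12, 2, 2)])
def test_kmeans_equals_exhaustive_minimum_wcss(n, k, seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, 2))
    _, labels = L.kmeans_fit(points, k, seed=0, n_init=50)
    best, oracle = brute_force_min_wcss(points, k)
    assert wcss(points, labels) == pytest.approx(best, rel=1e-9)
    assert partitions_equal(labels, oracle)


def test_centroid_matrix_rows_are_training_centroids(blobs3):
    points, truth = blobs3
    cm = L.build_centroid_matrix(L.consensus.EmbeddingResult(points, 2, 0, 0.0, 0),
                                 k=3, n_folds=5, seed=0)
    # every point in exactly one validation fold
    assert cm.fold_id.shape == (len(points),)
    assert set(np.unique(cm.fold_id)) == set(range(5))
    for f in range(5):
        rows = cm.assigned_centroid[cm.fold_id == f]
        fold_cents = cm.fold_centroids[f]
        for row in rows:
            assert np.min(np.linalg.norm(fold_cents - row, axis=1)) == 0.0


def test_centroid_matrix_stays_within_own_blob(blobs3):
    # 3 tight distant blobs: assigned centroid lies in the point's blob box
    points, truth = blobs3
    cm = L.build_centroid_matrix(points, k=3, n_folds=5, seed=1)
    for g in range(3):
        blob = points[truth == g]
        lo, hi = blob.min(axis=0) - 1e-9, blob.max(axis=0) + 1e-9
        assigned = cm.assigned_centroid[truth == g]
        assert np.all((assigned >= lo) & (assigned <= hi))


def test_centroid_matrix_single_fold_rejected(blobs3):
    points, _ = blobs3
    with pytest.raises(ValueError, match="fold"):
        L.build_centroid_matrix(points, k=3, n_folds=1, seed=0)


def test_consensus_on_identical_fold_centroids_is_nearest_centroid():
    # all folds produced the same centroid set: second pass must reduce to
    # nearest-centroid assignment to that common set (k-means on <=k
    # distinct points with k centers is exact)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    rng = np.random.default_rng(0)
    nearest = rng.integers(0, 3, size=60)
    cm = CentroidMatrix(assigned_centroid=centers[nearest],
                        fold_id=np.repeat(np.arange(5), 12), k=3,
                        fold_centroids=[centers] * 5)
    labels = L.consensus_labels(cm, 3, seed=0)
    assert partitions_equal(labels, nearest)


def test_consensus_invariant_to_fold_relabeling(blobs3):
    # fold labels never enter the computation: permuting the stored
    # per-fold centroid order leaves the final partition unchanged
    points, _ = blobs3
    cm = L.build_centroid_matrix(points, k=3, n_folds=5, seed=2)
    labels = L.consensus_labels(cm, 3, seed=0)
    relabeled = CentroidMatrix(
        assigned_centroid=cm.assigned_centroid.copy(),
        fold_id=cm.fold_id.copy(), k=3,
        fold_centroids=[fc[::-1].copy() for fc in cm.fold_centroids])
    labels2 = L.consensus_labels(relabeled, 3, seed=0)
    np.testing.assert_array_equal(labels, labels2)


def test_consensus_recovers_blobs_and_is_fold_seed_stable(blobs3):
    points, truth = blobs3
    runs = []
    for fold_seed in (0, 99):
        cm = L.build_centroid_matrix(points, k=3, n_folds=5, seed=fold_seed)
        runs.append(L.consensus_labels(cm, 3, seed=0))
    assert partitions_equal(runs[0], truth)
    assert adjusted_rand_score(runs[0], runs[1]) == pytest.approx(1.0)


def test_canonical_labels_ordered_by_cluster_size():
    labels = canonicalize_labels(np.array([2, 2, 2, 0, 0, 1]))
    np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 2])


def silhouette_oracle(points, labels):
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    vals = []
    for i in range(n):
        own = labels == labels[i]
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(d[i, labels == other].mean()
                for other in np.unique(labels) if other != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def db_oracle(points, labels):
    uniq = np.unique(labels)
    cents = np.array([points[labels == u].mean(axis=0) for u in uniq])
    sig = np.array([np.linalg.norm(points[labels == u] - c, axis=1).mean()
                    for u, c in zip(uniq, cents)])
    ratios = []
    for i in range(len(uniq)):
        ratios.append(max((sig[i] + sig[j]) / np.linalg.norm(cents[i] - cents[j])
                          for j in range(len(uniq)) if j != i))
    return float(np.mean(ratios))


def ch_oracle(points, labels):
    n, k = len(points), len(np.unique(labels))
    overall = points.mean(axis=0)
    between = sum((labels == u).sum() * np.linalg.norm(points[labels == u].mean(axis=0) - overall) ** 2
                  for u in np.unique(labels))
    within = sum(((points[labels == u] - points[labels == u].mean(axis=0)) ** 2).sum()
                 for u in np.unique(labels))
    return float((between / (k - 1)) / (within / (n - k)))


def test_quality_metrics_match_direct_formula_oracles():
    points = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.5],
                       [8.0, 8.0], [8.0, 9.0], [9.0, 8.5]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    q = L.cluster_quality(points, labels)
    assert q["silhouette"] == pytest.approx(silhouette_oracle(points, labels), abs=1e-9)
    assert q["davies_bouldin"] == pytest.approx(db_oracle(points, labels), abs=1e-9)
    assert q["calinski_harabasz"] == pytest.approx(ch_oracle(points, labels), abs=1e-9)


def test_quality_limiting_and_degenerate_cases():
    far = np.array([[0.0, 0.0], [0.01, 0.0], [100.0, 0.0], [100.01, 0.0]])
    q = L.cluster_quality(far, [0, 0, 1, 1])
    assert q["silhouette"] > 0.99
    rng = np.random.default_rng(5)
    blob = rng.normal(size=(80, 2))
    q_rand = L.cluster_quality(blob, rng.integers(0, 2, 80))
    assert abs(q_rand["silhouette"]) < 0.1
    with pytest.raises(ValueError):
        L.cluster_quality(blob, np.zeros(80))


def test_embedding_determinism_and_preconditions(blobs3):
    points, truth = blobs3
    rng = np.random.default_rng(0)
    X = np.hstack([points, rng.normal(scale=0.5, size=(len(points), 3))])
    e1 = L.fit_embedding(X, n_components=2, n_neighbors=10, min_dist=0.1, seed=4)
    e2 = L.fit_embedding(X, n_components=2, n_neighbors=10, min_dist=0.1, seed=4)
    np.testing.assert_array_equal(e1.coords, e2.coords)
    assert np.all(np.isfinite(e1.coords))
    # separation: mean inter-blob embedding distance > mean intra-blob
    d = np.linalg.norm(e1.coords[:, None] - e1.coords[None, :], axis=2)
    same = truth[:, None] == truth[None, :]
    np.fill_diagonal(same, False)
    assert d[~same & ~np.eye(len(X), dtype=bool)].mean() > d[same].mean()
    with pytest.raises(ValueError, match="n_neighbors"):
        L.fit_embedding(X[:5], n_neighbors=10)


def test_grid_search_selects_known_k_on_blobs(blobs3):
    points, truth = blobs3
    best, table = L.grid_search(
        points, {"n_components": [2], "n_neighbors": [10], "min_dist": [0.1],
                 "k": [2, 3, 4, 5]}, seed=0)
    assert best["k"] == 3
    assert len(table) == 4
    assert (table["status"] == "ok").all()


def test_grid_search_single_configuration_returned(blobs3):
    points, _ = blobs3
    best, table = L.grid_search(
        points, {"n_components": [2], "n_neighbors": [10], "min_dist": [0.1],
                 "k": [3]}, seed=0)
    assert best == {"n_components": 2, "n_neighbors": 10, "min_dist": 0.1, "k": 3}
    assert len(table) == 1


def test_stratify_rerun_reproducible_and_small_n_fails_gracefully(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(ValueError):
        L.stratify(cohort.head(30), k=3, n_neighbors=40)
    a = L.stratify(cohort, k=3, n_neighbors=15, seed=8)
    b = L.stratify(cohort, k=3, n_neighbors=15, seed=8)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.quality == b.quality
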