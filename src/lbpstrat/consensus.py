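"""Cross-validated consensus k-means over a UMAP embedding.

The stratification algorithm: (1) embed the robust-scaled feature matrix
with UMAP; (2) split the embedded points into five folds; for each fold,
fit k-means on the other four folds and record, for every held-out point,
the coordinates of its nearest training centroid; (3) run a second-pass
k-means on the resulting n x d centroid matrix to obtain final labels
that are invariant to each fold's arbitrary label numbering; (4) score the
partition with silhouette, Davies-Bouldin, and Calinski-Harabasz indices.
Hyperparameters (UMAP components / neighbors / min_dist and k) are chosen
by grid search.

The embedding is fit once on the full feature matrix; only the k-means
stage is cross-validated.  Centroids from fold-specific embeddings would
live in incomparable coordinate frames, which would make the second-pass
clustering of stacked centroid rows meaningless.  A per-fold-embedding
mode is available behind ``refit_embedding_per_fold`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    pairwise_distances_argmin,
    silhouette_score,
)
from sklearn.model_selection import KFold

from lbpstrat.preprocess import FeatureMatrix, assemble_features


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    n_components: int
    n_neighbors: int
    min_dist: float
    seed: int


@dataclass
class CentroidMatrix:
    """Per-point held-out centroid coordinates from the five-fold pass."""

    assigned_centroid: np.ndarray  # n x d
    fold_id: np.ndarray            # n, in 0..n_folds-1
    k: int
    fold_centroids: list = field(default_factory=list)  # per fold, k x d


@dataclass
class ConsensusResult:
    labels: np.ndarray
    k: int
    centroid_matrix: CentroidMatrix
    quality: dict
    hyperparams: dict
    seed_bundle: dict
    embedding: EmbeddingResult | None = None


def fit_embedding(features, n_components=7, n_neighbors=20, min_dist=0.3,
                  seed=0) -> EmbeddingResult:
    """UMAP embedding of the (scaled) feature matrix.

    Deterministic for a fixed ``seed`` (which forces single-threaded
    layout optimization).  Requires at least ``n_neighbors + 1`` rows.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {n}")
    import umap  # deferred: numba JIT import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=n_components, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return EmbeddingResult(coords=coords, n_components=n_components,
                           n_neighbors=n_neighbors, min_dist=min_dist, seed=seed)


def kmeans_fit(points, k, seed=0, n_init=10):
    """Lloyd's k-means with k-means++ initialization, best of ``n_init``
    restarts by within-cluster sum of squares.

    Returns ``(centroids, labels)`` with centroids of shape (k, d).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if X.shape[0] < k:
        raise ValueError(f"cannot fit {k} clusters to {X.shape[0]} points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
                tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    return km.cluster_centers_.copy(), labels


def build_centroid_matrix(embedding, k, n_folds=5, seed=0, n_init=10) -> CentroidMatrix:
    """Five-fold held-out centroid recording.

    Points are shuffled into ``n_folds`` disjoint validation folds; for
    each fold, k-means is fit on the remaining points and every held-out
    point receives the coordinates of its nearest training centroid.
    """
    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else np.asarray(embedding, dtype=float)
    n = coords.shape[0]
    if n_folds < 2:
        raise ValueError("need at least 2 folds (1 fold leaves no training data)")
    if n < n_folds * k:
        raise ValueError(f"n={n} too small for {n_folds} folds of {k} clusters")

    assigned = np.empty_like(coords)
    fold_id = np.empty(n, dtype=int)
    fold_centroids = []
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (train_idx, val_idx) in enumerate(splitter.split(coords)):
        centroids, _ = kmeans_fit(coords[train_idx], k, seed=seed + f, n_init=n_init)
        nearest = pairwise_distances_argmin(coords[val_idx], centroids)
        assigned[val_idx] = centroids[nearest]
        fold_id[val_idx] = f
        fold_centroids.append(centroids)
    return CentroidMatrix(assigned_centroid=assigned, fold_id=fold_id, k=k,
                          fold_centroids=fold_centroids)


def consensus_labels(cm: CentroidMatrix, k=None, seed=0, n_init=10) -> np.ndarray:
    """Second-pass k-means on the centroid matrix.

    Only centroid *coordinates* enter, so the result is invariant to the
    arbitrary label numbering inside each fold.  ``k`` defaults to the
    fold-level k.  Labels are canonicalized by descending cluster size.
    """
    if k is None:
        k = cm.k
    rows = cm.assigned_centroid
    distinct = np.unique(rows, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(f"only {distinct.shape[0]} distinct centroid rows; "
                         f"cannot form {k} consensus clusters")
    _, labels = kmeans_fit(rows, k, seed=seed, n_init=n_init)
    return canonicalize_labels(labels)


def canonicalize_labels(labels) -> np.ndarray:
    """Relabel clusters as 0, 1, ... in order of descending size
    (ties broken by first appearance)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    first_seen = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first_seen, -counts))
    mapping = {int(uniq[o]): rank for rank, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


def cluster_quality(points, labels) -> dict:
    """Internal-validity metrics of a partition.

    Silhouette (mean of (b-a)/max(a,b)), Davies-Bouldin index (lower is
    better), and Calinski-Harabasz score (higher is better).  Requires at
    least 2 non-empty clusters.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("quality metrics need at least 2 clusters")
    return {
        "silhouette": float(silhouette_score(X, labels)),
        "davies_bouldin": float(davies_bouldin_score(X, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
    }


def grid_search(features, grid, seed=0, n_folds=5, n_init=10):
    """Run the full embed -> centroid-matrix -> consensus -> quality
    pipeline for every configuration in ``grid``.

    ``grid`` maps the keys ``n_components``, ``n_neighbors``, ``min_dist``,
    ``k`` to lists of candidate values.  Configurations infeasible for the
    sample size are skipped (an error is raised only if all are).
    Selection rule: highest silhouette, ties broken by lower
    Davies-Bouldin, then higher Calinski-Harabasz.

    Returns ``(best: dict, table: DataFrame)`` where ``table`` has one row
    per attempted configuration.
    """
    keys = ("n_components", "n_neighbors", "min_dist", "k")
    grid = {key: list(np.atleast_1d(grid.get(key, _GRID_DEFAULTS[key]))) for key in keys}
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty for every hyperparameter")

    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    rows = []
    embeddings = {}
    for d in grid["n_components"]:
        for nn in grid["n_neighbors"]:
            for md in grid["min_dist"]:
                emb_key = (int(d), int(nn), float(md))
                for k in grid["k"]:
                    cfg = {"n_components": int(d), "n_neighbors": int(nn),
                           "min_dist": float(md), "k": int(k)}
                    try:
                        if emb_key not in embeddings:
                            embeddings[emb_key] = fit_embedding(
                                X, n_components=int(d), n_neighbors=int(nn),
                                min_dist=float(md), seed=seed)
                        emb = embeddings[emb_key]
                        cm = build_centroid_matrix(emb, int(k), n_folds=n_folds,
                                                   seed=seed, n_init=n_init)
                        labels = consensus_labels(cm, int(k), seed=seed, n_init=n_init)
                        q = cluster_quality(emb.coords, labels)
                        rows.append({**cfg, **q, "status": "ok"})
                    except ValueError as exc:
                        rows.append({**cfg, "silhouette": np.nan, "davies_bouldin": np.nan,
                                     "calinski_harabasz": np.nan,
                                     "status": f"skipped: {exc}"})
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise ValueError("every grid configuration was infeasible")
    best_row = ok.sort_values(
        ["silhouette", "davies_bouldin", "calinski_harabasz"],
        ascending=[False, True, False], kind="mergesort").iloc[0]
    best = {key: best_row[key] for key in keys}
    best["k"] = int(best["k"])
    best["n_components"] = int(best["n_components"])
    best["n_neighbors"] = int(best["n_neighbors"])
    return best, table


_GRID_DEFAULTS = {"n_components": [7], "n_neighbors": [20], "min_dist": [0.3],
                  "k": [2, 3, 4, 5]}


def stratify(cohort, instrument="SBT", k=None, n_components=7, n_neighbors=20,
             min_dist=0.3, n_folds=5, n_init=10, seed=0, grid=None,
             include_risk_score=True, risk_score_column="instrument_total",
             refit_embedding_per_fold=False) -> ConsensusResult:
    """End-to-end stratification of a cohort table.

    Assembles and robust-scales the feature matrix, embeds it with UMAP,
    runs the five-fold centroid-matrix consensus k-means, and attaches
    internal-validity metrics.  If ``k`` is None, a grid search over
    ``grid`` (default k in 2..5 at the default UMAP setting) picks the
    hyperparameters.
    """
    fm = assemble_features(cohort, instrument=instrument,
                           include_risk_score=include_risk_score,
                           risk_score_column=risk_score_column)
    grid_table = None
    if k is None:
        search_grid = dict(grid or {})
        search_grid.setdefault("n_components", [n_components])
        search_grid.setdefault("n_neighbors", [n_neighbors])
        search_grid.setdefault("min_dist", [min_dist])
        search_grid.setdefault("k", _GRID_DEFAULTS["k"])
        best, grid_table = grid_search(fm, search_grid, seed=seed,
                                       n_folds=n_folds, n_init=n_init)
        n_components, n_neighbors, min_dist, k = (
            best["n_components"], best["n_neighbors"], best["min_dist"], best["k"])

    embedding = fit_embedding(fm, n_components=n_components,
                              n_neighbors=n_neighbors, min_dist=min_dist, seed=seed)
    if refit_embedding_per_fold:
        cm = _centroid_matrix_per_fold_embedding(fm, k, n_components, n_neighbors,
                                                 min_dist, n_folds, seed, n_init)
    else:
        cm = build_centroid_matrix(embedding, k, n_folds=n_folds, seed=seed,
                                   n_init=n_init)
    labels = consensus_labels(cm, k, seed=seed, n_init=n_init)
    quality = cluster_quality(embedding.coords, labels)
    result = ConsensusResult(
        labels=labels, k=int(k), centroid_matrix=cm, quality=quality,
        hyperparams={"n_components": int(n_components), "n_neighbors": int(n_neighbors),
                     "min_dist": float(min_dist), "k": int(k), "n_folds": int(n_folds),
                     "n_init": int(n_init),
                     "refit_embedding_per_fold": bool(refit_embedding_per_fold)},
        seed_bundle={"umap": int(seed), "folds": int(seed), "kmeans": int(seed)},
        embedding=embedding,
    )
    result.grid_table = grid_table
    return result


def _centroid_matrix_per_fold_embedding(fm, k, n_components, n_neighbors, min_dist,
                                        n_folds, seed, n_init):
    """Alternative mode: refit UMAP on each fold's training points and
    transform the held-out points into that fold's frame.  Centroid rows
    then live in fold-specific frames; retained for comparison only."""
    import umap

    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n = X.shape[0]
    if n < n_folds * k:
        raise ValueError(f"n={n} too small for {n_folds} folds of {k} clusters")
    assigned = np.empty((n, n_components))
    fold_id = np.empty(n, dtype=int)
    fold_centroids = []
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (train_idx, val_idx) in enumerate(splitter.split(X)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=n_components, n_neighbors=n_neighbors,
                                min_dist=min_dist, random_state=seed)
            train_coords = reducer.fit_transform(X[train_idx])
            val_coords = reducer.transform(X[val_idx])
        centroids, _ = kmeans_fit(np.asarray(train_coords, dtype=float), k,
                                  seed=seed + f, n_init=n_init)
        nearest = pairwise_distances_argmin(np.asarray(val_coords, dtype=float), centroids)
        assigned[val_idx] = centroids[nearest]
        fold_id[val_idx] = f
        fold_centroids.append(centroids)
    return CentroidMatrix(assigned_centroid=assigned, fold_id=fold_id, k=k,
                          fold_centroids=fold_centroids)
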