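"""t-SNE embedding of latent codes and window clustering with model
selection by average silhouette.

Latent codes are embedded to 2-D with Barnes-Hut t-SNE (perplexity 30,
euclidean metric). Because t-SNE is stochastic, the embedding+clustering
pair is repeated over independently seeded trials and the trial with the
largest average silhouette (AS) is kept. Candidate partitions come from
k-means and agglomerative sweeps over k plus DBSCAN; the winner maximizes
AS with ties broken by lower SSE. An AS of at least 0.4 is the
conventional threshold for calling a partition significant. AS and SSE
are computed in the 2-D embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .errors import ClusteringError, ValidationError

SIGNIFICANT_AS = 0.4  # partitions at or above this average silhouette


@dataclass
class EmbeddingRun:
    """One seeded 2-D embedding of the latent codes."""

    coordinates: np.ndarray
    perplexity: float
    trial_seed: int
    metric: str = "euclidean"


@dataclass
class ClusteringResult:
    """A labelled partition with its quality scores.

    ``labels`` uses -1 for DBSCAN noise points, which are excluded from
    AS/SSE and counted in ``n_excluded_outliers``.
    """

    method: str
    n_clusters: int
    labels: np.ndarray
    AS: float                      # NaN when undefined (single cluster)
    SSE: float
    n_excluded_outliers: int = 0
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(np.isfinite(self.AS) and self.AS >= SIGNIFICANT_AS)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette (b - a) / max(a, b); singletons score 0."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette undefined for a single cluster")
    if len(uniq) >= len(labels):
        raise ValidationError("silhouette undefined when every point is a singleton")
    return float(silhouette_score(points, labels, metric="euclidean"))


def sse(points: np.ndarray, labels: np.ndarray) -> float:
    """Sum of squared euclidean distances to own-cluster centroids."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        grp = points[labels == lab]
        total += float(np.sum((grp - grp.mean(axis=0)) ** 2))
    return total


def tsne_embed(latents: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> EmbeddingRun:
    """Barnes-Hut t-SNE to 2-D; deterministic given the seed."""
    latents = np.asarray(latents, dtype=float)
    n = latents.shape[0]
    if n <= 3 * perplexity:
        raise ValidationError(
            f"t-SNE needs more than 3 x perplexity points ({n} <= {3 * perplexity:g})"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, metric="euclidean",
        method="barnes_hut", init="pca", random_state=seed,
    ).fit_transform(latents)
    return EmbeddingRun(np.asarray(coords, dtype=float), perplexity, seed)


def _score(points: np.ndarray, labels: np.ndarray, method: str) -> ClusteringResult:
    mask = labels >= 0
    n_out = int(np.sum(~mask))
    kept_pts, kept_lab = points[mask], labels[mask]
    if kept_pts.shape[0] == 0 or len(np.unique(kept_lab)) < 1:
        raise ClusteringError(f"{method}: no clustered points")
    # a single cluster has no silhouette; record it with AS = NaN
    as_val = (silhouette(kept_pts, kept_lab)
              if len(np.unique(kept_lab)) >= 2 else float("nan"))
    return ClusteringResult(
        method=method,
        n_clusters=len(np.unique(kept_lab)),
        labels=labels,
        AS=as_val,
        SSE=sse(kept_pts, kept_lab),
        n_excluded_outliers=n_out,
    )


def _pick(results: Sequence[ClusteringResult]) -> ClusteringResult:
    """Max AS, ties by lower SSE, then fewer clusters, then method name."""
    if not results:
        raise ClusteringError("no candidate clusterings")
    def key(r: ClusteringResult):
        as_val = r.AS if np.isfinite(r.AS) else -np.inf
        return (-as_val, r.SSE, r.n_clusters, r.method)
    return min(results, key=key)


def select_method(results: Sequence[ClusteringResult]) -> ClusteringResult:
    """Pick the final clustering among candidate methods (AS first, SSE tie-break)."""
    return _pick(results)


def _check_embedding(points: np.ndarray) -> None:
    if np.allclose(points, points[0]):
        raise ClusteringError("degenerate embedding: all points identical")


def kmeans_sweep(embedding: EmbeddingRun | np.ndarray,
                 k_range: Iterable[int] = range(2, 11),
                 seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """Fit k-means for each k and keep the k with maximal AS."""
    points = _coords(embedding)
    _check_embedding(points)
    results = []
    for k in k_range:
        if not 2 <= k <= points.shape[0] - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(points)
        if len(np.unique(labels)) < 2:
            continue
        results.append(_score(points, labels, "kmeans"))
    return _pick(results)


def hierarchical_sweep(embedding: EmbeddingRun | np.ndarray,
                       k_range: Iterable[int] = range(2, 11),
                       linkage: str = "ward") -> ClusteringResult:
    """Agglomerative cuts over k; SSE computed against cluster centroids."""
    points = _coords(embedding)
    _check_embedding(points)
    results = []
    for k in k_range:
        if not 2 <= k <= points.shape[0] - 1:
            continue
        labels = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(points)
        sizes = np.bincount(labels)
        if len(sizes) < 2 or (sizes == 1).all():
            continue
        results.append(_score(points, labels, "hierarchical"))
    return _pick(results)


def estimate_dbscan_eps(points: np.ndarray, min_pts: int = 4) -> float:
    """k-distance elbow: the knee of the sorted min_pts-NN distance curve
    (point of maximum distance to the chord joining its endpoints)."""
    nn = NearestNeighbors(n_neighbors=min_pts).fit(points)
    dists = np.sort(nn.kneighbors(points)[0][:, -1])
    n = len(dists)
    if n < 3 or dists[-1] == dists[0]:
        return float(dists[-1]) or 1e-3
    x = np.arange(n, dtype=float) / (n - 1)
    y = (dists - dists[0]) / (dists[-1] - dists[0])
    knee = int(np.argmax(x - y)) if (x - y).max() > 0 else int(np.argmax(y - x))
    return float(max(dists[knee], 1e-12))


def dbscan_cluster(embedding: EmbeddingRun | np.ndarray, eps: float | None = None,
                   min_pts: int = 4) -> ClusteringResult:
    """DBSCAN with noise points excluded from AS/SSE and reported as outliers."""
    points = _coords(embedding)
    if eps is None:
        eps = estimate_dbscan_eps(points, min_pts)
    if eps <= 0:
        raise ValidationError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    core = labels[labels >= 0]
    if core.size == 0:
        raise ClusteringError("DBSCAN labelled every point as noise")
    return _score(points, labels, "dbscan")


def best_of_trials(latents: np.ndarray,
                   clusterer: Callable[[np.ndarray], ClusteringResult] | None = None,
                   n_trials: int = 100, perplexity: float = 30.0,
                   base_seed: int = 0) -> tuple[EmbeddingRun, ClusteringResult]:
    """Repeat seeded embed+cluster ``n_trials`` times; keep the largest-AS
    trial (ties: lower SSE, then lower seed)."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if clusterer is None:
        clusterer = kmeans_sweep
    best: tuple[float, float, int, EmbeddingRun, ClusteringResult] | None = None
    for trial in range(n_trials):
        seed = base_seed + trial
        run = tsne_embed(latents, perplexity=perplexity, seed=seed)
        result = clusterer(run.coordinates)
        as_val = result.AS if np.isfinite(result.AS) else -np.inf
        key = (-as_val, result.SSE, seed)
        if best is None or key < best[:3]:
            best = (*key, run, result)
    assert best is not None
    return best[3], best[4]


def _coords(embedding: EmbeddingRun | np.ndarray) -> np.ndarray:
    if isinstance(embedding, EmbeddingRun):
        return embedding.coordinates
    return np.asarray(embedding, dtype=float)


def comparison_table(results: Sequence[ClusteringResult]):
    """Method-comparison table (NC, AS, SSE, NEO per candidate)."""
    import pandas as pd

    return pd.DataFrame(
        [{"method": r.method, "NC": r.n_clusters, "AS": r.AS, "SSE": r.SSE,
          "NEO": r.n_excluded_outliers if r.method == "dbscan" else None}
         for r in results]
    )
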