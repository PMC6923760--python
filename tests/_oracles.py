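"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and libraries) they check:
silhouette and SSE are O(N^2)/double-loop translations of their
definitions, the Kruskal-Wallis H comes from the rank-sum formula, and
PageRank scores come from a dense eigen-decomposition.
"""

from __future__ import annotations

import numpy as np


def brute_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores.append(0.0)
            continue
        a = dist[i][own].sum() / (n_own - 1)
        b = min(dist[i][labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def brute_sse(points: np.ndarray, labels: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    total = 0.0
    for lab in set(labels.tolist()):
        grp = points[np.asarray(labels) == lab]
        centroid = grp.sum(axis=0) / len(grp)
        for row in grp:
            total += float(((row - centroid) ** 2).sum())
    return total


def kruskal_h_formula(groups: list[np.ndarray]) -> float:
    """H from the rank-sum formula with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank (1-based)
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts ** 3) - counts).sum())
    denom = 1.0 - ties / (n ** 3 - n)
    return h / denom if denom > 0 else float("nan")


def pagerank_eigen(matrix: np.ndarray, damping: float) -> np.ndarray:
    """Stationary scores of the damped chain via a dense eigen-solve."""
    p = np.asarray(matrix, dtype=float)
    k = p.shape[0]
    m = damping * p + (1.0 - damping) / k
    vals, vecs = np.linalg.eig(m.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()
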