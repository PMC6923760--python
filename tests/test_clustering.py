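import numpy as np
import pytest

from somnoclust.clustering import (
    ClusteringResult,
    best_of_trials,
    dbscan_cluster,
    hierarchical_sweep,
    kmeans_sweep,
    select_method,
    silhouette,
    sse,
    tsne_embed,
)
from somnoclust.errors import ClusteringError, ValidationError

from _oracles import brute_silhouette, brute_sse


def _perm_equal(a, b):
    """Same partition up to label permutation."""
    a, b = np.asarray(a), np.asarray(b)
    mapping = {}
    for x, y in zip(a, b):
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestSilhouette:
    def test_matches_brute_force_on_worked_instance(self):
        pts = np.array([(0, 0), (0, 1), (10, 0), (10, 1)], dtype=float)
        labels = np.array([0, 0, 1, 1])
        expected = brute_silhouette(pts, labels)
        assert silhouette(pts, labels) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(60, 2))
            labels = rng.integers(0, 4, size=60)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(pts, labels) == pytest.approx(
                brute_silhouette(pts, labels), abs=1e-9)

    def test_well_separated_clusters_approach_one(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (30, 2)),
                         rng.normal(100, 0.01, (30, 2))])
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette(pts, labels) > 0.99

    def test_random_labels_on_one_blob_score_near_zero(self):
        """Null oracle: arbitrary labels on a single Gaussian blob give
        |AS| < 0.1 across 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(80, 2))
            labels = rng.integers(0, 2, size=80)
            if len(np.unique(labels)) < 2:
                continue
            assert abs(silhouette(pts, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestSSE:
    def test_each_point_own_cluster_is_zero(self):
        pts = np.random.default_rng(1).normal(size=(6, 2))
        assert sse(pts, np.arange(6)) == 0.0

    def test_hand_arithmetic_two_point_cluster(self):
        assert sse(np.array([(0.0, 0.0), (2.0, 0.0)]), np.array([0, 0])) == pytest.approx(2.0)

    def test_matches_brute_force_double_loop(self, rng):
        pts = rng.normal(size=(100, 3))
        labels = rng.integers(0, 5, size=100)
        assert sse(pts, labels) == pytest.approx(brute_sse(pts, labels), abs=1e-9)


class TestTsneEmbed:
    def test_too_few_points_for_perplexity_rejected(self):
        with pytest.raises(ValidationError):
            tsne_embed(np.random.default_rng(2).normal(size=(50, 5)), perplexity=30)

    def test_same_seed_identical_coordinates(self, rng):
        latents = rng.normal(size=(120, 5))
        a = tsne_embed(latents, perplexity=10, seed=3)
        b = tsne_embed(latents, perplexity=10, seed=3)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_duplicated_points_stay_mutual_neighbors(self, rng):
        latents = rng.normal(size=(120, 5))
        latents[1] = latents[0]  # exact duplicate pair
        coords = tsne_embed(latents, perplexity=10, seed=4).coordinates
        d = np.linalg.norm(coords - coords[0], axis=1)
        d[0] = np.inf
        assert np.argmin(d) == 1
        d = np.linalg.norm(coords - coords[1], axis=1)
        d[1] = np.inf
        assert np.argmin(d) == 0


class TestSweeps:
    def test_kmeans_finds_two_tight_blobs(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(10, 0.3, (40, 2))])
        result = kmeans_sweep(pts, range(2, 7))
        assert result.n_clusters == 2
        assert result.AS > 0.9
        assert result.significant  # AS >= 0.4 significance rule

    def test_kmeans_near_zero_sse_at_k_equals_n_minus_one(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        result = kmeans_sweep(pts, [4])
        assert result.SSE < 1.0

    def test_degenerate_embedding_rejected(self):
        with pytest.raises(ClusteringError):
            kmeans_sweep(np.zeros((20, 2)), range(2, 4))

    def test_hierarchical_agrees_with_kmeans_on_blobs(self, blob_points):
        pts, _ = blob_points
        km = kmeans_sweep(pts, range(2, 7))
        hc = hierarchical_sweep(pts, range(2, 7))
        assert hc.n_clusters == km.n_clusters == 3
        assert _perm_equal(km.labels, hc.labels)

    def test_ward_and_average_linkage_agree_on_blobs(self, blob_points):
        pts, _ = blob_points
        ward = hierarchical_sweep(pts, range(2, 7), linkage="ward")
        avg = hierarchical_sweep(pts, range(2, 7), linkage="average")
        assert _perm_equal(ward.labels, avg.labels)

    @pytest.mark.parametrize("k_true", [2, 3, 4, 5, 6])
    def test_sweep_recovers_planted_cluster_count(self, k_true):
        """On well-separated blobs the AS-maximizing sweep recovers the
        planted k in at least 90% of 20 seeded draws."""
        from sklearn.datasets import make_blobs

        angles = 2 * np.pi * np.arange(k_true) / k_true
        centers = 15 * np.column_stack([np.cos(angles), np.sin(angles)])
        hits = 0
        for seed in range(20):
            pts, _ = make_blobs(n_samples=40 * k_true, centers=centers,
                                cluster_std=0.8, random_state=seed)
            hits += kmeans_sweep(pts, range(2, 11), seed=seed).n_clusters == k_true
        assert hits >= 18


class TestDBSCAN:
    def test_huge_eps_single_cluster_no_outliers(self, blob_points):
        pts, _ = blob_points
        result = dbscan_cluster(pts, eps=1e6, min_pts=4)
        assert result.n_clusters == 1
        assert result.n_excluded_outliers == 0
        assert np.isnan(result.AS)  # silhouette undefined for one cluster

    def test_isolated_point_is_sole_outlier(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.3, (30, 2)),
                         rng.normal(10, 0.3, (30, 2)),
                         [[500.0, 500.0]]])
        result = dbscan_cluster(pts, eps=1.5, min_pts=4)
        assert result.n_excluded_outliers == 1
        assert result.labels[-1] == -1

    def test_as_excludes_noise_points(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.3, (30, 2)),
                         rng.normal(10, 0.3, (30, 2)),
                         [[500.0, 500.0]]])
        result = dbscan_cluster(pts, eps=1.5, min_pts=4)
        mask = result.labels >= 0
        assert result.AS == pytest.approx(
            brute_silhouette(pts[mask], result.labels[mask]), abs=1e-9)

    def test_all_noise_rejected(self):
        pts = np.arange(20, dtype=float).reshape(10, 2) * 100
        with pytest.raises(ClusteringError):
            dbscan_cluster(pts, eps=1e-6, min_pts=4)


class TestSelection:
    def _res(self, method, nc, as_, sse_, neo=0):
        return ClusteringResult(method, nc, np.zeros(4, dtype=int), as_, sse_, neo)

    def test_method_comparison_table_selects_best_as_then_sse(self):
        """On the six-row comparison the k-means diachronic entry (AS
        0.4653, SSE 21.5532) dominates and must be selected."""
        rows = [
            self._res("dbscan", 1, 0.2075, 119.4467, 14),
            self._res("hierarchical", 4, 0.3394, 35.0190),
            self._res("kmeans", 5, 0.3941, 22.6103),
            self._res("dbscan", 4, 0.1275, 64.7179, 30),
            self._res("hierarchical", 6, 0.4485, 24.3988),
            self._res("kmeans", 6, 0.4653, 21.5532),
        ]
        winner = select_method(rows)
        assert winner.method == "kmeans"
        assert winner.AS == pytest.approx(0.4653)
        assert winner.SSE == pytest.approx(21.5532)
        assert winner.significant

    def test_single_candidate_returned(self):
        only = self._res("kmeans", 2, 0.5, 1.0)
        assert select_method([only]) is only

    def test_equal_as_lower_sse_wins(self):
        a = self._res("kmeans", 3, 0.5, 2.0)
        b = self._res("hierarchical", 3, 0.5, 1.0)
        assert select_method([a, b]) is b

    def test_selection_invariant_to_input_order(self):
        rows = [self._res("kmeans", k, 0.1 * k, 50.0 - k) for k in range(2, 7)]
        fwd = select_method(rows)
        rev = select_method(rows[::-1])
        assert fwd is rev


@pytest.fixture(scope="module")
def blob_latents():
    rng = np.random.default_rng(8)
    centers = rng.normal(0, 20, size=(3, 15))
    return np.vstack([c + rng.normal(0, 0.5, (50, 15)) for c in centers])


class TestBestOfTrials:
    def test_single_trial_equals_direct_call(self, blob_latents):
        run, result = best_of_trials(blob_latents, n_trials=1, perplexity=10,
                                     base_seed=42)
        direct = tsne_embed(blob_latents, perplexity=10, seed=42)
        assert np.array_equal(run.coordinates, direct.coordinates)
        assert result.AS == pytest.approx(
            kmeans_sweep(direct.coordinates, range(2, 11)).AS)

    def test_winner_dominates_all_trials(self, blob_latents):
        _, best = best_of_trials(blob_latents, n_trials=3, perplexity=10,
                                 base_seed=0)
        for seed in range(3):
            run = tsne_embed(blob_latents, perplexity=10, seed=seed)
            trial = kmeans_sweep(run.coordinates, range(2, 11))
            assert best.AS >= trial.AS - 1e-12

    def test_separated_blobs_win_with_high_as(self, blob_latents):
        _, best = best_of_trials(blob_latents, n_trials=2, perplexity=10,
                                 base_seed=1)
        assert best.AS > 0.7
        assert best.n_clusters == 3
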