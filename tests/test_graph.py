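"""Distance matrix, threshold graph, and geodesic approximation."""

import numpy as np
import pytest

import sinosort as ss
from sinosort.features import fft_features
from sinosort.graph import DisconnectedGraphError, merge_duplicate_rows


def _floyd_warshall(weights):
    """Reference all-pairs shortest paths, scalar triple loop."""
    n = weights.shape[0]
    dist = weights.copy()
    dist[dist == 0] = np.inf
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j]:
                    dist[i, j] = via
    return dist


def _random_metric(rng, n):
    pts = rng.normal(size=(n, 3))
    return np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))


class TestPairwiseL2:
    def test_zero_diagonal_and_345(self):
        rows = np.array([[3.0, 4.0], [0.0, 0.0], [1.0, 1.0]])
        d = ss.pairwise_l2(rows)
        assert np.diag(d).max() == 0.0
        assert abs(d[0, 1] - 5.0) < 1e-12

    def test_matches_scalar_loop_reference(self):
        rng = np.random.default_rng(0)
        vectors = rng.normal(size=(10, 7)) + 1j * rng.normal(size=(10, 7))
        weights = rng.uniform(1, 2, size=7)
        d = ss.pairwise_l2(vectors, weights)
        for i in range(10):
            for j in range(10):
                ref = np.sqrt(sum(w * abs(vectors[i, k] - vectors[j, k]) ** 2
                                  for k, w in enumerate(weights)))
                assert abs(d[i, j] - ref) < 1e-12

    def test_symmetry_and_nonnegativity(self):
        d = ss.pairwise_l2(np.random.default_rng(1).normal(size=(6, 4)))
        np.testing.assert_array_equal(d, d.T)
        assert (d >= 0).all()


class TestBuildGraph:
    def test_large_threshold_gives_complete_graph(self):
        d = _random_metric(np.random.default_rng(2), 8)
        g = ss.build_graph(d, d.max() * 2)
        assert g.n_edges == 8 * 7 // 2

    def test_tiny_threshold_raises_disconnected(self):
        d = _random_metric(np.random.default_rng(3), 6)
        tiny = d[d > 0].min()
        with pytest.raises(DisconnectedGraphError) as excinfo:
            ss.build_graph(d, tiny)  # strict <, so even the closest pair drops
        assert sum(excinfo.value.component_sizes) == 6
        assert excinfo.value.suggested_threshold > 0

    def test_toy_matrix_exact_edge_set(self):
        d = np.array([[0.0, 1.0, 5.0, 4.0],
                      [1.0, 0.0, 2.0, 6.0],
                      [5.0, 2.0, 0.0, 3.0],
                      [4.0, 6.0, 3.0, 0.0]])
        g = ss.build_graph(d, 4.5)
        adj = g.adjacency.toarray()
        expected = {(0, 1), (1, 2), (2, 3), (0, 3)}
        got = {(i, j) for i in range(4) for j in range(i + 1, 4) if adj[i, j]}
        assert got == expected


class TestAutoThreshold:
    def test_points_on_a_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        assert abs(ss.auto_threshold(d) - 1.1) < 1e-12

    def test_equidistant_points(self):
        d = np.full((5, 5), 2.0)
        np.fill_diagonal(d, 0.0)
        assert abs(ss.auto_threshold(d) - 2.2) < 1e-12

    def test_agrees_with_incremental_connectivity_search(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = _random_metric(rng, rng.integers(5, 15))
            minimax = ss.auto_threshold(d, safety=1.0)
            # brute force: smallest pairwise distance whose graph connects
            candidates = np.unique(d[d > 0])
            for c in candidates:
                try:
                    ss.build_graph(d, np.nextafter(c, np.inf))
                    break
                except DisconnectedGraphError:
                    continue
            assert abs(minimax - c) < 1e-12


class TestGeodesics:
    def test_chain_distance_adds(self):
        d = np.array([[0.0, 1.0, 9.0], [1.0, 0.0, 1.0], [9.0, 1.0, 0.0]])
        g = ss.build_graph(d, 2.0)  # 1-3 edge excluded
        m = ss.geodesic_distances(g)
        assert abs(m[0, 2] - 2.0) < 1e-12

    def test_complete_metric_graph_returns_input(self):
        d = _random_metric(np.random.default_rng(5), 12)
        g = ss.build_graph(d, d.max() * 2)
        np.testing.assert_allclose(ss.geodesic_distances(g), d, atol=1e-12)

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(5, 51))
            d = _random_metric(rng, n)
            threshold = ss.auto_threshold(d, safety=float(rng.uniform(1.05, 1.6)))
            g = ss.build_graph(d, threshold)
            ref = _floyd_warshall(g.adjacency.toarray())
            np.testing.assert_allclose(ss.geodesic_distances(g), ref,
                                       atol=1e-10)

    def test_triangle_inequality_exact(self):
        d = _random_metric(np.random.default_rng(7), 15)
        g = ss.build_graph(d, ss.auto_threshold(d))
        m = ss.geodesic_distances(g)
        slack = m[:, :, None] + m[None, :, :] - m[:, None, :]
        assert slack.min() > -1e-10

    def test_growing_threshold_never_increases_geodesics(self):
        d = _random_metric(np.random.default_rng(8), 20)
        t0 = ss.auto_threshold(d)
        m_small = ss.geodesic_distances(ss.build_graph(d, t0))
        m_large = ss.geodesic_distances(ss.build_graph(d, 2 * t0))
        assert (m_large <= m_small + 1e-12).all()


class TestManifoldLocality:
    def test_uniform_angle_neighbors_are_angular_neighbors(self, phantom):
        n = 128
        angles = 2 * np.pi * np.arange(n) / n
        sino = ss.radon_project(phantom, angles, 299)
        d = ss.pairwise_l2(fft_features(sino))
        hits = 0
        for i in range(n):
            nearest = set(np.argsort(d[i])[1:3].tolist())
            hits += nearest == {(i - 1) % n, (i + 1) % n}
        assert hits / n >= 0.95


class TestMergeDuplicates:
    def test_exact_duplicates_collapse_to_one_node(self):
        base = np.random.default_rng(9).normal(size=(4, 3))
        rows = np.vstack([base, base[1]])  # row 4 duplicates row 1
        d = ss.pairwise_l2(rows)
        reps, membership = merge_duplicate_rows(d)
        assert len(reps) == 4
        assert membership[4] == membership[1]
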