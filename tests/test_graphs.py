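"""Wavelet-band and graph-metric tests: MODWT energy identity and band
isolation, density thresholding against a sort oracle, clustering and path
length against enumeration oracles, and degree-preserving nulls."""

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from pspdyn.graphs import (
    band_frequency_range,
    boundary_coef_count,
    char_path_length,
    clustering_coefficient,
    degree_preserving_randomize,
    graph_metrics,
    modwt,
    modwt_detail,
    normalize_metric,
    regional_weighted_degree,
    threshold_density,
    wavelet_correlation_matrix,
)


def clustering_bruteforce(adj):
    """Per-node triangle enumeration, independent of networkx."""
    R = adj.shape[0]
    out = np.zeros(R)
    for i in range(R):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        tri = sum(adj[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1 :])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


class TestBands:
    @pytest.mark.parametrize(
        "tr,level,expected",
        [(2.0, 2, (0.0625, 0.125)), (2.5, 2, (0.05, 0.10)), (2.0, 1, (0.125, 0.25))],
    )
    def test_dyadic_band_edges(self, tr, level, expected):
        lo, hi = band_frequency_range(tr, level)
        assert (lo, hi) == pytest.approx(expected)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            band_frequency_range(0.0, 2)


class TestMODWT:
    def test_constant_series_zero_details(self):
        details, smooth = modwt(np.full(64, 3.0), level=2)
        for d in details:
            assert np.abs(d).max() < 1e-10

    def test_energy_decomposition(self, rng):
        """MODWT with periodic boundary partitions the series energy."""
        x = rng.standard_normal(128)
        details, smooth = modwt(x, level=3)
        energy = sum((d**2).sum() for d in details) + (smooth**2).sum()
        assert energy == pytest.approx((x**2).sum(), rel=1e-10)

    def test_band_isolation_of_sinusoid(self):
        """A 0.09 Hz tone at TR=2 falls in the level-2 band (0.0625-0.125 Hz).

        A length-8 Daubechies filter is used here: band isolation sharpens
        with filter length, and the short default D4 filter leaks more
        across adjacent bands.
        """
        t = np.arange(512) * 2.0
        x = np.sin(2 * np.pi * 0.09 * t)
        v = [modwt_detail(x, lev, wavelet="db4").var() for lev in (1, 2, 3)]
        assert v[1] > 5 * v[0]
        assert v[1] > 5 * v[2]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            modwt_detail(np.ones(10), level=3)


class TestWaveletCorrelation:
    def test_identical_and_negated_channels(self, rng):
        x = rng.standard_normal(200)
        X = np.column_stack([x, x, -x])
        M = wavelet_correlation_matrix(X, level=2).matrix
        assert M[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert M[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.allclose(np.diag(M), 1.0)

    def test_independent_channels_near_zero(self):
        vals = []
        for s in range(15):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((300, 2))
            vals.append(abs(wavelet_correlation_matrix(X, level=2).matrix[0, 1]))
        assert np.median(vals) < 0.25

    def test_zero_variance_detail_rejected(self, rng):
        X = np.column_stack([rng.standard_normal(128), np.full(128, 2.0)])
        with pytest.raises(ValueError):
            wavelet_correlation_matrix(X, level=2)

    def test_boundary_count(self):
        # db2 has filter length 4: (2^2 - 1)*3 + 1 = 10 at level 2
        assert boundary_coef_count(2, "db2") == 10


class TestThresholdDensity:
    def test_edge_count(self, rng):
        M = rng.random((5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        adj, _ = threshold_density(M, 0.2)
        assert adj.sum() // 2 == 2  # round(0.2 * 10)

    def test_full_density_complete_graph(self, rng):
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        adj, _ = threshold_density(M, 1.0)
        assert adj.sum() // 2 == 15

    def test_matches_sort_oracle(self, rng):
        R = 12
        M = rng.standard_normal((R, R))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        adj, retained = threshold_density(M, 0.3)
        iu = np.triu_indices(R, 1)
        k = round(0.3 * len(iu[0]))
        top = set(
            sorted(zip(M[iu], iu[0], iu[1]), key=lambda t: -t[0])[:k][i][1:] for i in range(k)
        )
        got = set(zip(iu[0][adj[iu]], iu[1][adj[iu]]))
        assert got == top
        assert np.allclose(retained[adj], M[adj])

    def test_monotone_edge_nesting_across_densities(self, rng):
        """Edges retained at a lower density are a subset of those at a
        higher density (1%-10% robustness sweep)."""
        R = 30
        M = rng.standard_normal((R, R))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        prev = None
        for d in (0.01, 0.02, 0.05, 0.10):
            adj, _ = threshold_density(M, d)
            edges = set(zip(*np.nonzero(np.triu(adj))))
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_zero_edges_rejected(self, rng):
        M = np.eye(4)
        with pytest.raises(ValueError):
            threshold_density(M, 0.01)


class TestGraphMetricOracles:
    def test_complete_graph_clustering(self):
        per, mean = clustering_coefficient(nx.complete_graph(4))
        assert np.allclose(per, 1.0)
        assert mean == 1.0

    def test_star_graph_clustering(self):
        _, mean = clustering_coefficient(nx.star_graph(5))
        assert mean == 0.0

    def test_complete_graph_path_length(self):
        assert char_path_length(nx.complete_graph(5)) == 1.0

    def test_cycle_path_length(self):
        assert char_path_length(nx.cycle_graph(4)) == pytest.approx(4 / 3)

    def test_random_graphs_match_bruteforce(self):
        """Both metrics equal independent enumeration/BFS oracles on 50
        random graphs."""
        for s in range(50):
            rng = np.random.default_rng(s)
            R = int(rng.integers(8, 26))
            p = rng.uniform(0.15, 0.5)
            G = nx.gnp_random_graph(R, p, seed=int(rng.integers(0, 2**31)))
            adj = nx.to_numpy_array(G).astype(bool)
            per, mean = clustering_coefficient(G)
            want = clustering_bruteforce(adj)
            assert np.allclose(per, want, atol=1e-12)
            D = shortest_path(adj.astype(float), method="D", unweighted=True)
            finite = np.isfinite(D) & (D > 0)
            if finite.any():
                assert char_path_length(G) == pytest.approx(D[finite].mean())

    def test_no_reachable_pairs_rejected(self):
        with pytest.raises(ValueError):
            char_path_length(nx.empty_graph(4))


class TestNullModels:
    def test_degree_sequence_preserved(self, rng):
        G = nx.gnp_random_graph(20, 0.3, seed=4)
        want = sorted(d for _, d in G.degree())
        for s in range(5):
            Gn = degree_preserving_randomize(G, seed=s)
            assert sorted(d for _, d in Gn.degree()) == want
            assert not any(Gn.has_edge(v, v) for v in Gn)

    def test_triangle_unchanged(self):
        G = nx.complete_graph(3)
        Gn = degree_preserving_randomize(G, seed=0)
        assert set(Gn.edges()) == set(G.edges())

    def test_lattice_clustering_exceeds_nulls(self):
        G = nx.watts_strogatz_graph(30, 6, 0.0, seed=0)  # pure lattice
        _, c = clustering_coefficient(G)
        nulls = [
            clustering_coefficient(degree_preserving_randomize(G, seed=s))[1] for s in range(30)
        ]
        assert normalize_metric(c, nulls) > 1.0

    def test_normalize_identity(self):
        assert normalize_metric(2.0, [2.0] * 100) == 1.0

    def test_normalize_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_metric(1.0, [0.0] * 100)


class TestRegionalDegree:
    def test_complete_graph_equal_weights(self):
        R, w = 6, 0.5
        M = np.full((R, R), w)
        np.fill_diagonal(M, 0.0)
        out = regional_weighted_degree(M, {"all": list(range(R))})
        assert out["all"] == pytest.approx((R - 1) * w)

    def test_isolated_node_zero(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 1.0
        out = regional_weighted_degree(M, {"a": [0, 1], "b": [2]})
        assert out["b"] == 0.0

    def test_row_sum_oracle(self, rng):
        M = rng.random((8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        part = {"x": [0, 1, 2], "y": [3, 4, 5, 6, 7]}
        out = regional_weighted_degree(M, part)
        assert out["x"] == pytest.approx(M.sum(axis=1)[:3].mean())

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            regional_weighted_degree(np.zeros((2, 2)), {"a": [], "b": [0, 1]})


def test_graph_metrics_end_to_end(rng):
    """The combined helper produces finite, internally consistent output."""
    X = rng.standard_normal((256, 12))
    from pspdyn.graphs import wavelet_correlation_matrix

    assoc = wavelet_correlation_matrix(X, level=2, tr=2.0)
    gm = graph_metrics(assoc, density=0.25, n_null=20, seed=0)
    assert gm.weighted_degree.shape == (12,)
    assert gm.density == 0.25
    assert gm.path_length_raw >= 1.0
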