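"""Adjacency construction and small-world metrics against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegsmallworld.montage import CHANNELS_1020
from eegsmallworld.network import (
    NetworkMetrics,
    RandomReference,
    average_path_length,
    build_adjacency,
    clustering_coefficient,
    count_connections,
    edge_count,
    epoch_metrics,
    network_size,
    normalized_metrics,
    random_reference,
)

# ---------------------------------------------------------------------------
# oracles


def bfs_path_oracle(adj):
    """Mean shortest path over reachable pairs of present nodes (BFS)."""
    n = len(adj)
    present = [i for i in range(n) if any(adj[i][j] for j in range(n) if j != i)]
    dists = []
    for s in present:
        seen = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if v != u and adj[u][v] and v not in seen:
                        seen[v] = seen[u] + 1
                        nxt.append(v)
            frontier = nxt
        dists.extend(d for t, d in seen.items() if t != s and t in present)
    return sum(dists) / len(dists) if dists else 1.0


def triangle_clustering_oracle(adj):
    """Watts-Strogatz clustering by exhaustive neighbour-pair counting."""
    n = len(adj)
    present = [i for i in range(n) if any(adj[i][j] for j in range(n) if j != i)]
    if len(present) < 2:
        return 0.0
    vals = []
    for i in present:
        nbrs = [j for j in present if j != i and adj[i][j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b]
        )
        vals.append(links / (len(nbrs) * (len(nbrs) - 1) / 2))
    return sum(vals) / len(vals)


def adj_from_edges(n, edges, diag=()):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
        a[i, i] = a[j, j] = True
    for d in diag:
        a[d, d] = True
    return a


# ---------------------------------------------------------------------------


class TestBuildAdjacency:
    def test_shared_bin_makes_complete_matrix(self):
        presence = np.zeros((19, 49), dtype=bool)
        presence[:, 18] = True  # 10 Hz everywhere
        adj = build_adjacency(presence)
        assert adj.all() and count_connections(adj) == 361

    def test_pairwise_intersections(self):
        presence = np.zeros((19, 49), dtype=bool)
        presence[0, 18] = True  # A: 10 Hz
        presence[1, 18] = True  # B: 10 Hz
        presence[2, 6] = True  # C: 4 Hz alone
        adj = build_adjacency(presence)
        assert adj[0, 1] and adj[1, 0]
        assert adj[0, 0] and adj[1, 1] and adj[2, 2]
        assert count_connections(adj) == 5
        assert edge_count(adj) == 1
        assert network_size(adj) == 2

    def test_empty_peaksets_zero_matrix(self):
        adj = build_adjacency(np.zeros((19, 49), dtype=bool))
        assert not adj.any()
        assert network_size(adj) == 0

    def test_lone_oscillating_electrode_is_no_network(self):
        adj = adj_from_edges(19, [], diag=[4])
        assert network_size(adj) == 0 and count_connections(adj) == 1


class TestRawMetrics:
    def test_triangle_fully_clustered(self):
        adj = adj_from_edges(19, [(0, 1), (1, 2), (0, 2)])
        assert clustering_coefficient(adj) == 1.0
        assert average_path_length(adj) == 1.0

    def test_star_has_zero_clustering(self):
        adj = adj_from_edges(19, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficient(adj) == 0.0

    def test_three_node_path_length(self):
        adj = adj_from_edges(19, [(0, 1), (1, 2)])
        assert average_path_length(adj) == pytest.approx(4 / 3)

    def test_five_node_example_matches_oracle(self):
        edges = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]
        adj = adj_from_edges(5, edges)
        assert clustering_coefficient(adj) == pytest.approx(
            triangle_clustering_oracle(adj.tolist())
        )
        assert average_path_length(adj) == pytest.approx(bfs_path_oracle(adj.tolist()))

    def test_matches_networkx_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1 << 30)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 2:
                continue
            adj = nx.to_numpy_array(g).astype(bool)
            np.fill_diagonal(adj, True)
            assert clustering_coefficient(adj) == pytest.approx(
                nx.average_clustering(g)
            )
            # networkx: mean over pairs within each connected component
            total, pairs = 0.0, 0
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                if len(comp) < 2:
                    continue
                sp = dict(nx.all_pairs_shortest_path_length(sub))
                for s, targets in sp.items():
                    for t, d in targets.items():
                        if s != t:
                            total += d
                            pairs += 1
            assert average_path_length(adj) == pytest.approx(total / pairs)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        adj = rng.random((12, 12)) < 0.25
        adj |= adj.T
        perm = rng.permutation(12)
        padj = adj[np.ix_(perm, perm)]
        for f in (network_size, count_connections, clustering_coefficient,
                  average_path_length):
            assert f(adj) == pytest.approx(f(padj))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(seed)
        adj = rng.random((10, 10)) < 0.3
        adj |= adj.T
        c = clustering_coefficient(adj)
        l = average_path_length(adj)
        assert 0.0 <= c <= 1.0
        assert 1.0 <= l <= 9.0 or (network_size(adj) < 2 and l == 1.0)


class TestRandomReference:
    def test_complete_graph_reference_is_unity(self):
        assert random_reference(5, 10, n_rand=10, seed=3) == (1.0, 1.0)

    def test_empty_reference_uses_degenerate_conventions(self):
        assert random_reference(4, 0, n_rand=10, seed=3) == (0.0, 1.0)

    def test_impossible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            random_reference(4, 7)

    def test_matches_exhaustive_average(self):
        # n=6, m=7: average over all C(15,7)=6435 labelled graphs
        n, m = 6, 7
        pairs = list(itertools.combinations(range(n), 2))
        c_all, l_all = [], []
        for chosen in itertools.combinations(pairs, m):
            adj = adj_from_edges(n, chosen)
            c_all.append(clustering_coefficient(adj))
            l_all.append(average_path_length(adj))
        c_exact, l_exact = np.mean(c_all), np.mean(l_all)
        c_mc, l_mc = random_reference(n, m, n_rand=200, seed=7)
        assert c_mc == pytest.approx(c_exact, abs=4 * np.std(c_all) / np.sqrt(200))
        assert l_mc == pytest.approx(l_exact, abs=4 * np.std(l_all) / np.sqrt(200))

    def test_seeded_and_cached(self):
        ref = RandomReference(n_rand=20, seed=9)
        a = ref.mean_metrics(8, 12)
        b = ref.mean_metrics(8, 12)
        assert a == b
        assert a == RandomReference(n_rand=20, seed=9).mean_metrics(8, 12)


class TestNormalizedMetrics:
    def test_degenerate_network_conventions(self):
        adj = adj_from_edges(19, [], diag=[0])
        m = normalized_metrics(adj)
        assert (m.C_raw, m.L_raw, m.SWI, m.SWI_raw) == (0.0, 1.0, 0.0, 0.0)
        assert np.isnan(m.C_rel) and np.isnan(m.L_rel)

    def test_self_normalisation_of_complete_graph(self):
        adj = adj_from_edges(6, list(itertools.combinations(range(6), 2)))
        m = normalized_metrics(adj)
        assert m.C_rel == m.L_rel == m.SWI == 1.0

    def test_swi_is_ratio_of_relative_metrics(self):
        adj = adj_from_edges(19, [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5)])
        m = normalized_metrics(adj, RandomReference(n_rand=100, seed=2))
        assert m.SWI == pytest.approx(m.C_rel / m.L_rel)
        assert m.SWI_raw == pytest.approx(m.C_raw / m.L_raw)
        assert m.C_rel > 0 and m.L_rel > 0


class TestEpochMetrics:
    def test_mean_of_constant_series(self):
        adj = adj_from_edges(19, [(0, 1), (1, 2), (0, 2)])
        per_sec = [normalized_metrics(adj) for _ in range(5)]
        avg = epoch_metrics(per_sec)
        assert avg.C_raw == per_sec[0].C_raw
        assert avg.network_size == 3.0

    def test_alternating_complete_and_empty(self):
        complete = np.ones((19, 19), dtype=bool)
        empty = np.zeros((19, 19), dtype=bool)
        series = [normalized_metrics(a) for a in [complete, empty] * 5]
        avg = epoch_metrics(series)
        assert avg.network_size == pytest.approx(9.5)
        # relative metrics defined only on the complete seconds
        assert avg.C_rel == pytest.approx(1.0)

    def test_single_valid_second_dominates_missing(self):
        complete = np.ones((19, 19), dtype=bool)
        empty = np.zeros((19, 19), dtype=bool)
        series = [normalized_metrics(empty)] * 4 + [normalized_metrics(complete)]
        avg = epoch_metrics(series)
        assert avg.L_rel == pytest.approx(1.0)
        assert avg.SWI == pytest.approx(1.0 / 5)  # four degenerate zeros

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            epoch_metrics([])
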