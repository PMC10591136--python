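"""Paths, centralities, k-core, clustering — against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

import holenet as hn
from holenet.exceptions import CapabilityError, ValidationError

from conftest import to_networkx


# ---------------------------------------------------------------------------
# independent oracles


def brute_betweenness(g):
    """Enumerate every shortest path explicitly and count interiors."""
    nodes = list(g.nodes)
    score = {v: 0.0 for v in nodes}
    dist_from = {s: hn.multi_source_dijkstra(g, [s], weighted=False).dist
                 for s in nodes}

    def all_shortest_paths(s, t):
        d = dist_from[s]
        if math.isinf(d[t]):
            return []
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append(list(reversed(acc + [s])))
                return
            for u in (g.pred[v] if g.directed else g.adj[v]):
                if d.get(u, math.inf) == d[v] - 1:
                    walk(u, acc + [v])

        walk(t, [])
        return paths

    pairs = (combinations(nodes, 2) if not g.directed
             else [(s, t) for s in nodes for t in nodes if s != t])
    for s, t in pairs:
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def naive_core_numbers(g):
    """Repeated peeling from scratch for every k."""
    core = {v: 0 for v in g.nodes}
    k = 0
    while True:
        k += 1
        work = g.copy()  # directed peeling uses total (in+out) degree
        while True:
            doomed = [v for v in work.nodes if work.degree(v, "total") < k]
            if not doomed:
                break
            for v in doomed:
                work.remove_node(v)
        if work.n_nodes == 0:
            return core
        for v in work.nodes:
            core[v] = k


# ---------------------------------------------------------------------------
# shortest paths


class TestDijkstra:
    def test_path_graph(self, path3):
        dm = hn.multi_source_dijkstra(path3, [0], weighted=False)
        assert dm[2] == 2

    def test_weighted_detour(self):
        g = hn.Graph()
        g.add_edge("a", "b", weight=1)
        g.add_edge("b", "c", weight=1)
        g.add_edge("a", "d", weight=5)
        g.add_edge("d", "c", weight=1)
        dm = hn.multi_source_dijkstra(g, ["a"])
        assert dm["c"] == 2.0

    def test_all_sources_zero(self, triangle):
        dm = hn.multi_source_dijkstra(triangle, list(triangle.nodes))
        assert all(d == 0.0 for d in dm.dist.values())

    def test_unreachable_is_infinity(self):
        g = hn.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        dm = hn.multi_source_dijkstra(g, [0])
        assert math.isinf(dm[2])

    def test_empty_sources_rejected(self, triangle):
        with pytest.raises(ValidationError):
            hn.multi_source_dijkstra(triangle, [])

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_floyd_warshall(self, directed):
        for seed in range(30):
            g = hn.random_weighted(20, 45, directed=directed, seed=seed)
            nodes = list(g.nodes)
            idx = {v: i for i, v in enumerate(nodes)}
            W = np.full((len(nodes), len(nodes)), np.inf)
            np.fill_diagonal(W, 0.0)
            for u, v, d in g.edges():
                W[idx[u], idx[v]] = min(W[idx[u], idx[v]], d["weight"])
                if not directed:
                    W[idx[v], idx[u]] = min(W[idx[v], idx[u]], d["weight"])
            D = floyd_warshall(W)
            sources = nodes[:3]
            dm = hn.multi_source_dijkstra(g, sources)
            for v in nodes:
                expect = min(D[idx[s], idx[v]] for s in sources)
                assert dm[v] == pytest.approx(expect, abs=1e-9)


# ---------------------------------------------------------------------------
# betweenness


class TestBetweenness:
    def test_path_midpoint(self, path3):
        assert hn.betweenness_centrality(path3)[1] == 1.0

    def test_star_center(self, star3):
        assert hn.betweenness_centrality(star3)[0] == 3.0

    def test_complete_graph_zero(self):
        bc = hn.betweenness_centrality(hn.fixture("complete", n=5))
        assert all(x == 0.0 for x in bc.scores.values())

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_path_enumeration(self, directed):
        for seed in range(30):
            g = hn.erdos_renyi_gnm(10, 18, directed=directed, seed=seed)
            ours = hn.betweenness_centrality(g).scores
            brute = brute_betweenness(g)
            for v in g.nodes:
                assert ours[v] == pytest.approx(brute[v], abs=1e-9)

    def test_sampled_all_sources_equals_full(self):
        g = hn.erdos_renyi_gnm(25, 60, seed=7)
        full = hn.betweenness_centrality(g).scores
        sampled = hn.betweenness_centrality(g, sources=list(g.nodes)).scores
        assert full == pytest.approx(sampled)

    def test_normalization(self, path3):
        bc = hn.betweenness_centrality(path3, normalized=True)
        assert bc[1] == pytest.approx(1.0)  # (n-1)(n-2)/2 = 1

    def test_matches_networkx(self, karate):
        import networkx as nx
        ours = hn.betweenness_centrality(karate, normalized=True).scores
        ref = nx.betweenness_centrality(to_networkx(karate))
        for v in karate.nodes:
            assert ours[v] == pytest.approx(ref[v], abs=1e-9)


# ---------------------------------------------------------------------------
# closeness


class TestCloseness:
    def test_path_midpoint(self, path3):
        assert hn.closeness_centrality(path3)[1] == 1.0

    def test_complete_all_one(self):
        cc = hn.closeness_centrality(hn.fixture("complete", n=6))
        assert all(x == 1.0 for x in cc.scores.values())

    def test_componentwise_convention(self):
        g = hn.Graph()
        g.add_edge("a", "b")
        g.add_edge("c", "d")
        cc = hn.closeness_centrality(g)
        assert all(x == 1.0 for x in cc.scores.values())

    def test_isolated_node_zero(self):
        g = hn.Graph()
        g.add_node("x")
        assert hn.closeness_centrality(g)["x"] == 0.0

    def test_sampled_equals_full_on_subset(self):
        g = hn.erdos_renyi_gnm(30, 70, seed=1)
        full = hn.closeness_centrality(g).scores
        some = hn.closeness_centrality(g, sources=list(g.nodes)[:10]).scores
        for v in some:
            assert some[v] == full[v]


# ---------------------------------------------------------------------------
# pagerank


class TestPagerank:
    def test_symmetric_cases(self):
        pr = hn.pagerank(hn.fixture("complete", n=3))
        assert all(x == pytest.approx(1 / 3) for x in pr.scores.values())
        g = hn.Graph(directed=True)
        g.add_edge("a", "b")
        g.add_edge("b", "a")
        pr = hn.pagerank(g)
        assert pr["a"] == pytest.approx(0.5)

    def test_directed_chain_matches_power_iteration(self):
        g = hn.Graph(directed=True)
        g.add_edge("a", "b")
        g.add_edge("b", "c")
        pr = hn.pagerank(g, damping=0.85, tol=1e-12)
        # dense-matrix power-method oracle with dangling redistribution
        P = np.zeros((3, 3))
        P[1, 0] = 1.0  # a -> b
        P[2, 1] = 1.0  # b -> c
        x = np.full(3, 1 / 3)
        for _ in range(200):
            dangling = x[2]
            x = (1 - 0.85) / 3 + 0.85 * (P @ x + dangling / 3)
        for v, i in zip("abc", range(3)):
            assert pr[v] == pytest.approx(x[i], abs=1e-9)

    def test_sums_to_one_and_relabel_invariant(self):
        g = hn.erdos_renyi_gnm(40, 100, directed=True, seed=9)
        pr = hn.pagerank(g)
        assert sum(pr.scores.values()) == pytest.approx(1.0, abs=1e-9)
        relabeled = hn.Graph(directed=True)
        for u, v, d in g.edges():
            relabeled.add_edge(f"n{u}", f"n{v}", **d)
        for v in g.nodes:
            relabeled.add_node(f"n{v}")
        pr2 = hn.pagerank(relabeled)
        for v in g.nodes:
            assert pr2[f"n{v}"] == pytest.approx(pr[v], abs=1e-9)

    def test_bad_damping(self, triangle):
        with pytest.raises(ValidationError):
            hn.pagerank(triangle, damping=1.0)


# ---------------------------------------------------------------------------
# k-core


class TestKCore:
    def test_triangle_with_pendant(self, triangle):
        triangle.add_edge(0, 3)
        cores = hn.k_core(triangle).core
        assert cores == {0: 2, 1: 2, 2: 2, 3: 1}

    def test_complete_graph(self):
        cores = hn.k_core(hn.fixture("complete", n=5)).core
        assert all(c == 4 for c in cores.values())

    def test_edgeless(self):
        g = hn.Graph()
        for i in range(4):
            g.add_node(i)
        assert all(c == 0 for c in hn.k_core(g).core.values())

    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_naive_peeling(self, directed):
        for seed in range(30):
            g = hn.erdos_renyi_gnm(30, 70, directed=directed, seed=seed)
            assert hn.k_core(g).core == naive_core_numbers(g)

    def test_core_bounded_by_degree_and_monotone(self):
        g = hn.erdos_renyi_gnm(40, 80, seed=4)
        before = hn.k_core(g).core
        for v in g.nodes:
            assert before[v] <= g.degree(v)
        g.add_edge(0, 39) if not g.has_edge(0, 39) else g.add_edge(1, 38)
        after = hn.k_core(g).core
        assert all(after[v] >= before[v] for v in g.nodes)


# ---------------------------------------------------------------------------
# clustering and triangles


class TestClustering:
    def test_triangle_node(self, triangle):
        assert hn.local_clustering(triangle, 0) == 1.0

    def test_star_center(self, star3):
        assert hn.local_clustering(star3, 0) == 0.0

    def test_partial_neighborhood(self):
        g = hn.Graph()
        for x in "abc":
            g.add_edge("v", x)
        g.add_edge("a", "b")
        assert hn.local_clustering(g, "v") == pytest.approx(1 / 3)

    def test_missing_node(self, triangle):
        with pytest.raises(KeyError):
            hn.local_clustering(triangle, "nope")

    def test_triangle_counts(self, broker4):
        assert hn.triangle_count(hn.fixture("complete", n=4)) == 4
        assert hn.triangle_count(broker4) == 8
        assert hn.triangle_count(hn.fixture("path", n=6)) == 0

    def test_directed_triangles_rejected(self):
        g = hn.Graph(directed=True)
        g.add_edge(0, 1)
        with pytest.raises(CapabilityError):
            hn.triangle_count(g)

    def test_matches_networkx_clustering(self, karate):
        import networkx as nx
        ref = nx.clustering(to_networkx(karate))
        for v in karate.nodes:
            assert hn.local_clustering(karate, v) == pytest.approx(ref[v])


class TestStructure:
    def test_connected_components(self):
        g = hn.Graph()
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        g.add_node(4)
        comps = hn.connected_components(g)
        assert sorted(sorted(c) for c in comps) == [[0, 1], [2, 3], [4]]

    def test_articulation_points(self, broker4):
        # broker 8 plus its two contact nodes are the cut vertices
        assert hn.articulation_points(broker4) == {0, 4, 8}

    def test_articulation_matches_networkx(self):
        import networkx as nx
        for seed in range(20):
            g = hn.erdos_renyi_gnm(15, 20, seed=seed)
            ours = hn.articulation_points(g)
            ref = set(nx.articulation_points(to_networkx(g)))
            assert ours == ref

    def test_diameter(self, path3):
        assert hn.diameter(path3) == 2
        g = hn.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        assert math.isinf(hn.diameter(g))
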