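"""Burt metrics closed forms and spanner-detector invariants."""

import math

import networkx as nx
import pytest

import holenet as hn
from holenet.exceptions import UndefinedStatisticError, ValidationError

from conftest import to_networkx

DETECTORS_NEEDING_PARTITION = ("his", "maxd", "weaktie_local", "weaktie_bi")


def run_detector(name, g, partition, k=1):
    if name == "his":
        return hn.detect_his(g, partition, k=k)
    if name == "maxd":
        return hn.detect_maxd(g, partition, k=k)
    if name == "greedy":
        return hn.detect_greedy(g, k=k)
    if name == "ap_greedy":
        return hn.detect_ap_greedy(g, k=k)
    if name == "icc":
        return hn.detect_icc(g, k=k)
    if name == "bicc":
        return hn.detect_bicc(g, k=k, bound=2)
    if name == "ap_bicc":
        return hn.detect_ap_bicc(g, k=k)
    if name.startswith("weaktie"):
        return hn.detect_weak_tie(g, partition, k=k,
                                  variant=name.split("_")[1])
    raise AssertionError(name)


def broker_setup(k):
    g = hn.two_cliques_bridge(k)
    broker = 2 * k
    part = hn.CommunityPartition(blocks=[set(range(k)) | {broker},
                                         set(range(k, 2 * k))])
    return g, broker, part


# ---------------------------------------------------------------------------
# Burt metrics


class TestTieStrengths:
    def test_sums_to_one_on_random_weighted(self):
        for seed in range(40):
            g = hn.random_weighted(15, 30, seed=seed)
            for v in g.nodes:
                p = hn.tie_strengths(g, v)
                if p:
                    assert sum(p.values()) == pytest.approx(1.0)
                    assert all(x >= 0 for x in p.values())

    def test_directed_uses_symmetrized_weights(self):
        g = hn.Graph(directed=True)
        g.add_edge("a", "b", weight=2.0)
        g.add_edge("b", "a", weight=1.0)
        g.add_edge("a", "c", weight=3.0)
        p = hn.tie_strengths(g, "a")
        assert p["b"] == pytest.approx(3 / 6)
        assert p["c"] == pytest.approx(3 / 6)


class TestClosedForms:
    def test_star_center(self, star3):
        assert hn.effective_size(star3, 0) == pytest.approx(3.0)
        assert hn.efficiency(star3, 0) == pytest.approx(1.0)
        assert hn.constraint(star3, 0) == pytest.approx(1 / 3)
        assert hn.hierarchy(star3, 0) == 0.0

    def test_triangle_node(self, triangle):
        assert hn.effective_size(triangle, 0) == pytest.approx(1.0)
        assert hn.efficiency(triangle, 0) == pytest.approx(0.5)
        assert hn.constraint(triangle, 0) == pytest.approx(1.125)

    def test_pendant_leaf(self, path3):
        assert hn.effective_size(path3, 0) == pytest.approx(1.0)
        assert hn.efficiency(path3, 0) == pytest.approx(1.0)
        assert hn.constraint(path3, 0) == pytest.approx(1.0)
        assert hn.hierarchy(path3, 0) == 0.0  # degree-1 convention

    def test_unequal_constraint_hierarchy_hand_computed(self):
        # broker b tied to a pendant p and to both members of a 2-clique
        g = hn.Graph()
        g.add_edge("b", "p")
        g.add_edge("b", "x")
        g.add_edge("b", "y")
        g.add_edge("x", "y")
        terms = {"p": (1 / 3) ** 2,
                 "x": (1 / 3 + (1 / 3) * (1 / 2)) ** 2,
                 "y": (1 / 3 + (1 / 3) * (1 / 2)) ** 2}
        C = sum(terms.values())
        N = 3
        expected = sum((c / (C / N)) * math.log(c / (C / N))
                       for c in terms.values()) / (N * math.log(N))
        assert hn.constraint(g, "b") == pytest.approx(C)
        assert hn.hierarchy(g, "b") == pytest.approx(expected)
        assert hn.hierarchy(g, "b") > 0

    def test_isolated_node_undefined(self):
        g = hn.Graph()
        g.add_node("x")
        for fn in (hn.effective_size, hn.efficiency, hn.constraint):
            with pytest.raises(UndefinedStatisticError):
                fn(g, "x")

    def test_matches_networkx_on_karate(self, karate):
        ref_es = nx.effective_size(to_networkx(karate))
        ref_c = nx.constraint(to_networkx(karate))
        for v in karate.nodes:
            assert hn.effective_size(karate, v) == pytest.approx(ref_es[v])
            assert hn.constraint(karate, v) == pytest.approx(ref_c[v])


class TestMetricProperties:
    def test_effective_size_bounds(self):
        for seed in range(20):
            g = hn.random_weighted(12, 25, seed=seed)
            for v in g.nodes:
                deg = len(set(g.neighbors(v)) - {v})
                if deg == 0:
                    continue
                es = hn.effective_size(g, v)
                assert 1.0 - 1e-9 <= es <= deg + 1e-9
                assert 0.0 < hn.efficiency(g, v) <= 1.0 + 1e-9
                assert -1e-9 <= hn.hierarchy(g, v) <= 1.0 + 1e-9

    def test_constraint_decreases_with_star_growth(self):
        prev = None
        for leaves in range(1, 10):
            g = hn.fixture("star", leaves=leaves)
            c = hn.constraint(g, 0)
            if prev is not None:
                assert c < prev
            prev = c


# ---------------------------------------------------------------------------
# detectors


ALL_SEVEN = ("his", "maxd", "greedy", "ap_greedy", "icc", "bicc", "ap_bicc")


class TestBrokerInvariant:
    @pytest.mark.parametrize("name", ALL_SEVEN)
    @pytest.mark.parametrize("k_clique", [3, 4, 5])
    def test_detectors_rank_broker_first(self, name, k_clique):
        g, broker, part = broker_setup(k_clique)
        table = run_detector(name, g, part)
        assert table.top[0] == broker

    @pytest.mark.parametrize("variant", ["local", "bi"])
    @pytest.mark.parametrize("k_clique", [3, 4, 5])
    def test_weak_tie_broker_maximal(self, variant, k_clique):
        g, broker, part = broker_setup(k_clique)
        table = hn.detect_weak_tie(g, part, variant=variant)
        assert table.scores[broker] == max(table.scores.values())
        assert table.scores[broker] > 0

    def test_greedy_and_ap_greedy_agree(self):
        for k_clique in (3, 4, 5):
            g, broker, _ = broker_setup(k_clique)
            assert (hn.detect_greedy(g, k=1).top
                    == hn.detect_ap_greedy(g, k=1).top)


class TestGreedyFamily:
    def test_path_cut_vertex(self, path3):
        assert hn.detect_greedy(path3, k=1).top == [1]
        assert hn.detect_ap_greedy(path3, k=1).top == [1]

    def test_complete_graph_all_zero(self):
        g = hn.fixture("complete", n=5)
        table = hn.detect_greedy(g, k=1)
        assert all(s == 0.0 for s in table.scores.values())
        assert table.top == [0]  # tie-break: smallest label

    def test_scores_match_exhaustive_removal_oracle(self):
        g = hn.erdos_renyi_gnm(12, 20, seed=11)
        n = g.n_nodes
        table = hn.detect_greedy(g, k=1)
        for v in g.nodes:
            # oracle: all-pairs BFS sums with and without v
            def pair_sum(graph, skip):
                nodes = [u for u in graph.nodes if u != skip]
                total = 0.0
                for i, s in enumerate(nodes):
                    dm = hn.multi_source_dijkstra(graph, [s], weighted=False)
                    for t in nodes[i + 1:]:
                        d = dm[t]
                        total += n if math.isinf(d) else d
                return total
            g_minus = g.copy()
            g_minus.remove_node(v)
            g_minus_sum = 0.0
            nodes = [u for u in g_minus.nodes]
            for i, s in enumerate(nodes):
                dm = hn.multi_source_dijkstra(g_minus, [s], weighted=False)
                for t in nodes[i + 1:]:
                    d = dm[t]
                    g_minus_sum += n if math.isinf(d) else d
            expected = g_minus_sum - pair_sum(g, v)
            assert table.scores[v] == pytest.approx(expected, abs=1e-9)

    def test_k_bounds(self, triangle):
        with pytest.raises(ValidationError):
            hn.detect_greedy(triangle, k=3)


class TestIccFamily:
    def test_symmetric_graph_equal_scores(self):
        table = hn.detect_icc(hn.fixture("complete", n=4), k=1)
        vals = list(table.scores.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_bicc_with_large_bound_equals_icc(self):
        for seed in range(50):
            g = hn.erdos_renyi_gnm(15, 30, seed=seed)
            icc = hn.detect_icc(g, k=2).scores
            bound = 20  # >= any possible diameter of a 15-node graph
            bicc = hn.detect_bicc(g, k=2, bound=bound).scores
            for v in g.nodes:
                assert bicc[v] == pytest.approx(icc[v], abs=1e-9)

    def test_bicc_bound_validation(self, broker4):
        with pytest.raises(ValidationError):
            hn.detect_bicc(broker4, k=1, bound=0)

    def test_ap_bicc_zero_on_non_cut_nodes(self, broker4):
        table = hn.detect_ap_bicc(broker4, k=1)
        aps = hn.articulation_points(broker4)
        for v in broker4.nodes:
            if v not in aps:
                assert table.scores[v] == 0.0


class TestHis:
    def test_single_block_degenerate(self, triangle):
        part = hn.CommunityPartition(blocks=[{0, 1, 2}])
        table = hn.detect_his(triangle, part)
        assert table.flags
        assert all(s == 0.0 for s in table.scores.values())

    def test_disconnected_cliques_no_broker(self):
        g = hn.Graph()
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(i, j)
                g.add_edge(3 + i, 3 + j)
        part = hn.CommunityPartition(blocks=[{0, 1, 2}, {3, 4, 5}])
        table = hn.detect_his(g, part)
        # without any bridge no node accumulates cross-community importance
        assert max(table.scores.values()) == pytest.approx(0.0)

    def test_broker_strictly_highest(self):
        g, broker, part = broker_setup(4)
        table = hn.detect_his(g, part)
        others = [s for v, s in table.scores.items() if v != broker]
        assert table.scores[broker] > max(others)


class TestMaxD:
    def test_k_zero_empty_selection(self, broker4, broker_partition4):
        table = hn.detect_maxd(broker4, broker_partition4, k=0)
        assert table.top == []

    def test_disconnected_blocks_score_zero(self):
        g = hn.Graph()
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(i, j)
                g.add_edge(3 + i, 3 + j)
        part = hn.CommunityPartition(blocks=[{0, 1, 2}, {3, 4, 5}])
        table = hn.detect_maxd(g, part, k=2)
        assert all(s == 0.0 for s in table.scores.values())

    def test_needs_two_blocks(self, triangle):
        with pytest.raises(ValidationError):
            hn.detect_maxd(triangle,
                           hn.CommunityPartition(blocks=[{0, 1, 2}]), k=1)

    def test_broker_removal_disconnects(self, broker4, broker_partition4):
        table = hn.detect_maxd(broker4, broker_partition4, k=1)
        assert table.top == [8]
        g2 = broker4.copy()
        g2.remove_node(8)
        assert len(hn.connected_components(g2)) == 2


class TestWeakTie:
    def test_all_intra_ties_zero(self, triangle):
        part = hn.CommunityPartition(blocks=[{0, 1, 2}])
        table = hn.detect_weak_tie(triangle, part, variant="local")
        assert all(s == 0.0 for s in table.scores.values())
        assert table.flags

    def test_directed_unreciprocated_tie(self):
        g = hn.Graph(directed=True)
        g.add_edge("a", "b")
        part = hn.CommunityPartition(blocks=[{"a"}, {"b"}])
        bi = hn.detect_weak_tie(g, part, variant="bi")
        local = hn.detect_weak_tie(g, part, variant="local")
        assert bi.scores["a"] == 0.0
        assert local.scores["a"] > 0.0

    def test_local_downweights_embedded_ties(self):
        # a cross tie sharing a common neighbor counts less than a bare one
        g = hn.Graph()
        g.add_edge("a", "b")
        g.add_edge("a", "c")
        g.add_edge("b", "c")
        g.add_edge("a", "d")
        part = hn.CommunityPartition(blocks=[{"a", "c"}, {"b", "d"}])
        table = hn.detect_weak_tie(g, part, variant="local")
        # a-b is embedded (common neighbor c): 1/2; a-d is bare: 1
        assert table.scores["a"] == pytest.approx(0.5 + 1.0)


class TestDeterminism:
    @pytest.mark.parametrize("name", ALL_SEVEN + ("weaktie_local",))
    def test_relabeling_invariance(self, name):
        g, broker, part = broker_setup(4)
        mapping = {v: f"x{v}" for v in g.nodes}
        g2 = hn.Graph()
        for u, v, d in g.edges():
            g2.add_edge(mapping[u], mapping[v], **d)
        part2 = hn.CommunityPartition(
            blocks=[{mapping[v] for v in b} for b in part.blocks])
        t1 = run_detector(name, g, part)
        t2 = run_detector(name, g2, part2)
        for v in g.nodes:
            assert t2.scores[mapping[v]] == pytest.approx(t1.scores[v])

    def test_topk_tie_break_is_label_order(self):
        g = hn.fixture("complete", n=4)
        table = hn.detect_icc(g, k=3)
        assert table.top == sorted(table.top, key=str)
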