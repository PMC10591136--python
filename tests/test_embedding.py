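"""Node embeddings: separation, determinism, walk laws, edge cases."""

import numpy as np
import pytest
from scipy.stats import chisquare

import holenet as hn
from holenet.embedding import AliasTable, clique_separation
from holenet.exceptions import ValidationError


GROUPS6 = [set(range(6)), set(range(6, 12))]


def small_kwargs():
    return dict(d=16, walks_per_node=6, walk_length=20, window=4, epochs=2)


class TestWalks:
    def test_walks_start_at_designated_nodes(self):
        g = hn.two_cliques_bridge(4)
        corpus = hn.random_walks(g, walks_per_node=3, walk_length=10, seed=0)
        starts = [w[0] for w in corpus.walks]
        for v in g.nodes:
            assert starts.count(v) == 3

    def test_walks_follow_edges(self):
        g = hn.two_cliques_bridge(3)
        corpus = hn.random_walks(g, walks_per_node=2, walk_length=15, seed=1)
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                assert g.has_edge(a, b)

    def test_dead_end_truncates(self):
        g = hn.Graph(directed=True)
        g.add_edge("a", "b")  # b has no out-neighbors
        corpus = hn.random_walks(g, walks_per_node=1, walk_length=10, seed=0)
        for walk in corpus.walks:
            assert walk[-1] == "b"
            assert len(walk) <= 2

    def test_node2vec_unit_parameters_match_uniform_law(self):
        # with p=q=1 the biased second-order law collapses to the uniform
        # first-order law; compare step distributions on K4 by chi-square
        g = hn.fixture("complete", n=4)
        c1 = hn.random_walks(g, walks_per_node=60, walk_length=50, seed=3)
        c2 = hn.node2vec_walks(g, p=1.0, q=1.0, walks_per_node=60,
                               walk_length=50, seed=3)

        def transition_counts(corpus):
            counts = {}
            for walk in corpus.walks:
                for a, b in zip(walk, walk[1:]):
                    counts[(a, b)] = counts.get((a, b), 0) + 1
            return counts

        k1, k2 = transition_counts(c1), transition_counts(c2)
        keys = sorted(set(k1) | set(k2))
        obs = np.array([k2.get(k, 0) for k in keys], dtype=float)
        exp = np.array([k1.get(k, 0) for k in keys], dtype=float)
        exp = exp * obs.sum() / exp.sum()
        _, p_value = chisquare(obs, exp)
        assert p_value > 1e-4  # same law, not a significant difference

    def test_node2vec_invalid_parameters(self):
        g = hn.fixture("complete", n=3)
        with pytest.raises(ValidationError):
            hn.node2vec_walks(g, p=0.0)


class TestAliasTable:
    def test_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        table = AliasTable([1.0, 2.0, 7.0])
        draws = table.draw_many(rng, 30_000)
        freq = np.bincount(draws, minlength=3) / 30_000
        assert np.allclose(freq, [0.1, 0.2, 0.7], atol=0.02)

    def test_invalid_weights(self):
        with pytest.raises(ValidationError):
            AliasTable([])
        with pytest.raises(ValidationError):
            AliasTable([0.0, 0.0])


class TestTraining:
    @pytest.mark.parametrize("method", ["deepwalk", "node2vec", "line"])
    def test_clique_separation_positive(self, method):
        g = hn.two_cliques_bridge(6)
        wins = 0
        for seed in range(5):
            if method == "deepwalk":
                emb = hn.deepwalk(g, seed=seed, **small_kwargs())
            elif method == "node2vec":
                emb = hn.node2vec(g, p=0.5, q=2.0, seed=seed,
                                  **small_kwargs())
            else:
                emb = hn.line(g, d=16, order="1", samples=15_000, seed=seed)
            if clique_separation(emb, GROUPS6) > 0:
                wins += 1
        assert wins >= 3  # majority of seeds

    @pytest.mark.parametrize("method", ["deepwalk", "node2vec", "line"])
    def test_seed_determinism(self, method):
        g = hn.two_cliques_bridge(4)
        def run():
            if method == "deepwalk":
                return hn.deepwalk(g, d=8, walks_per_node=3, walk_length=10,
                                   seed=9)
            if method == "node2vec":
                return hn.node2vec(g, d=8, walks_per_node=3, walk_length=10,
                                   seed=9)
            return hn.line(g, d=8, samples=2_000, seed=9)
        assert np.array_equal(run().vectors, run().vectors)

    def test_vectors_finite_and_nonzero(self):
        g = hn.two_cliques_bridge(4)
        emb = hn.deepwalk(g, d=8, walks_per_node=4, walk_length=12, seed=2)
        assert np.all(np.isfinite(emb.vectors))
        assert not np.any(np.all(emb.vectors == 0, axis=1))

    def test_single_node_zero_vector(self):
        g = hn.Graph()
        g.add_node("x")
        emb = hn.deepwalk(g, d=8, seed=0)
        assert np.all(emb.vector("x") == 0)

    def test_line_zero_samples_returns_initialization(self):
        g = hn.two_cliques_bridge(3)
        emb = hn.line(g, d=8, order="1", samples=0, seed=4)
        assert np.all(np.isfinite(emb.vectors))
        assert emb.vectors.shape == (7, 8)

    def test_line_order_both_concatenates(self):
        g = hn.two_cliques_bridge(3)
        emb = hn.line(g, d=8, order="both", samples=500, seed=1)
        assert emb.vectors.shape == (7, 8)

    def test_line_odd_dimension_with_both_rejected(self):
        g = hn.fixture("complete", n=3)
        with pytest.raises(ValidationError):
            hn.line(g, d=7, order="both")

    def test_invalid_dimension(self):
        g = hn.fixture("complete", n=3)
        with pytest.raises(ValidationError):
            hn.deepwalk(g, d=0)

    def test_tsv_export_round_figures(self):
        g = hn.fixture("complete", n=3)
        emb = hn.deepwalk(g, d=4, walks_per_node=2, walk_length=5, seed=0)
        lines = emb.to_tsv().splitlines()
        assert len(lines) == 3
        assert all(len(line.split("\t")) == 5 for line in lines)
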