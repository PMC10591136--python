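"""Random-walk and edge-sampling node embeddings: DeepWalk, node2vec, LINE.

All three methods learn low-dimensional vectors in which nodes that are
close in the graph end up close in the embedding space:

* DeepWalk — uniform random walks fed to skip-gram with negative
  sampling (SGNS, unigram^0.75 noise distribution);
* node2vec — second-order biased walks (return parameter p, in-out
  parameter q, sampled through alias tables) with the same SGNS trainer;
  p = q = 1 recovers DeepWalk's walk law exactly;
* LINE — direct edge sampling (alias sampling proportional to edge
  weight) optimizing first-order proximity (shared vectors on the two
  endpoints) or second-order proximity (separate context vectors);
  ``order="both"`` trains two d/2 halves and concatenates them.

Training is plain SGD with a linearly decaying learning rate, done in a
single worker, so every method is bit-deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .graph import Graph

__all__ = ["EmbeddingMatrix", "WalkCorpus", "deepwalk", "node2vec", "line",
           "random_walks", "node2vec_walks"]


@dataclass
class WalkCorpus:
    """A bag of node-label walks plus the parameters that produced it."""

    walks: list
    walk_length: int
    walks_per_node: int
    seed: Optional[int] = None


@dataclass
class EmbeddingMatrix:
    """Node-by-dimension real matrix with the node ordering indexing it."""

    node_order: tuple
    vectors: np.ndarray
    d: int
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.node_order)}

    def vector(self, v) -> np.ndarray:
        return self.vectors[self._index[v]]

    def cosine(self, u, v) -> float:
        a, b = self.vector(u), self.vector(v)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b / (na * nb))

    def to_tsv(self) -> str:
        rows = []
        for v in self.node_order:
            vals = "\t".join(repr(float(x)) for x in self.vector(v))
            rows.append(f"{v}\t{vals}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# alias method (Walker) for O(1) discrete sampling


class AliasTable:
    """Walker's alias method: O(n) setup, O(1) draws."""

    def __init__(self, weights: Sequence[float]):
        w = np.asarray(weights, dtype=np.float64)
        if w.size == 0 or np.any(w < 0) or w.sum() == 0:
            raise ValidationError("alias table needs nonnegative weights "
                                  "with a positive sum")
        n = w.size
        prob = w * n / w.sum()
        self.prob = np.ones(n)
        self.alias = np.arange(n)
        small = [i for i in range(n) if prob[i] < 1.0]
        large = [i for i in range(n) if prob[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.prob[s] = prob[s]
            self.alias[s] = l
            prob[l] = prob[l] - (1.0 - prob[s])
            (small if prob[l] < 1.0 else large).append(l)

    def draw(self, rng: np.random.Generator) -> int:
        n = self.prob.size
        i = int(rng.integers(n))
        return i if rng.random() < self.prob[i] else int(self.alias[i])

    def draw_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.integers(self.prob.size, size=size)
        keep = rng.random(size) < self.prob[idx]
        return np.where(keep, idx, self.alias[idx])


# ---------------------------------------------------------------------------
# walk generation


def random_walks(g: Graph, walks_per_node: int = 10, walk_length: int = 80,
                 seed: Optional[int] = None) -> WalkCorpus:
    """Uniform random walks, *walks_per_node* starts from every node.

    Walks stop early at dead ends (nodes without out-neighbors).
    """
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    nbrs = {v: list(g.adj[v]) for v in nodes}
    walks = []
    for _ in range(walks_per_node):
        order = list(nodes)
        rng.shuffle(order)
        for start in order:
            walk = [start]
            while len(walk) < walk_length:
                cur = nbrs[walk[-1]]
                if not cur:
                    break
                walk.append(cur[int(rng.integers(len(cur)))])
            walks.append(walk)
    return WalkCorpus(walks=walks, walk_length=walk_length,
                      walks_per_node=walks_per_node, seed=seed)


def node2vec_walks(g: Graph, p: float = 1.0, q: float = 1.0,
                   walks_per_node: int = 10, walk_length: int = 80,
                   seed: Optional[int] = None) -> WalkCorpus:
    """Second-order biased walks: weight 1/p to return to the previous
    node, 1 to a common neighbor of previous and current, 1/q outward."""
    if p <= 0 or q <= 0:
        raise ValidationError("p and q must be positive")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    nbrs = {v: list(g.adj[v]) for v in nodes}
    nbr_sets = {v: set(g.adj[v]) for v in nodes}
    alias_cache: dict = {}

    def table(prev, cur) -> AliasTable:
        key = (prev, cur)
        if key not in alias_cache:
            w = []
            for x in nbrs[cur]:
                if x == prev:
                    w.append(1.0 / p)
                elif x in nbr_sets[prev]:
                    w.append(1.0)
                else:
                    w.append(1.0 / q)
            alias_cache[key] = AliasTable(w)
        return alias_cache[key]

    walks = []
    for _ in range(walks_per_node):
        order = list(nodes)
        rng.shuffle(order)
        for start in order:
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                if not nbrs[cur]:
                    break
                if len(walk) == 1:
                    nxt = nbrs[cur][int(rng.integers(len(nbrs[cur])))]
                else:
                    nxt = nbrs[cur][table(walk[-2], cur).draw(rng)]
                walk.append(nxt)
            walks.append(walk)
    return WalkCorpus(walks=walks, walk_length=walk_length,
                      walks_per_node=walks_per_node, seed=seed)


# ---------------------------------------------------------------------------
# SGNS trainer


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _init_vectors(n: int, d: int, rng: np.random.Generator,
                  trainable: np.ndarray) -> np.ndarray:
    """Uniform(-0.5/d, 0.5/d) rows for trainable nodes, zeros otherwise.

    A node that can never occur in a training pair (isolated) keeps the
    zero vector, so a single-node graph embeds to exactly zero.
    """
    vec = (rng.random((n, d)) - 0.5) / d
    vec[~trainable] = 0.0
    return vec


def _sgns_train(pairs: np.ndarray, n: int, d: int, negatives: int,
                epochs: int, counts: np.ndarray,
                rng: np.random.Generator, lr0: float = 0.025) -> np.ndarray:
    """Skip-gram with negative sampling over (center, context) pairs.

    Noise distribution is unigram frequency raised to 0.75.  Returns the
    input (center) vectors.
    """
    trainable = np.zeros(n, dtype=bool)
    if len(pairs):
        trainable[pairs[:, 0]] = True
        trainable[pairs[:, 1]] = True
    W = _init_vectors(n, d, rng, trainable)          # center vectors
    C = np.zeros((n, d))                             # context vectors
    noise = np.where(trainable, counts.astype(np.float64), 0.0) ** 0.75
    if noise.sum() == 0:
        return W
    alias = AliasTable(noise)
    total = epochs * len(pairs)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for i in order:
            lr = max(lr0 * (1.0 - step / max(total, 1)), lr0 * 1e-2)
            step += 1
            u, v = int(pairs[i, 0]), int(pairs[i, 1])
            negs = alias.draw_many(rng, negatives)
            targets = np.concatenate(([v], negs))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            wu = W[u]
            cv = C[targets]
            score = _sigmoid(cv @ wu)
            gradc = (score - labels)[:, None] * wu[None, :]
            gradw = (score - labels) @ cv
            C[targets] -= lr * gradc
            W[u] -= lr * gradw
    return W


def _pairs_from_walks(corpus: WalkCorpus, index: dict,
                      window: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = []
    counts = np.zeros(len(index), dtype=np.int64)
    for walk in corpus.walks:
        ids = [index[v] for v in walk]
        for i, u in enumerate(ids):
            counts[u] += 1
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((u, ids[j]))
    arr = (np.array(pairs, dtype=np.int64) if pairs
           else np.empty((0, 2), dtype=np.int64))
    return arr, counts


def deepwalk(g: Graph, d: int = 128, walks_per_node: int = 10,
             walk_length: int = 80, window: int = 5, negatives: int = 5,
             epochs: int = 1, seed: Optional[int] = None) -> EmbeddingMatrix:
    """DeepWalk: uniform walks + SGNS."""
    if d < 1:
        raise ValidationError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    corpus = random_walks(g, walks_per_node, walk_length,
                          seed=int(rng.integers(2 ** 31)))
    return _train_from_corpus(g, corpus, d, window, negatives, epochs, rng,
                              method="deepwalk",
                              params={"walks_per_node": walks_per_node,
                                      "walk_length": walk_length,
                                      "window": window, "seed": seed})


def node2vec(g: Graph, d: int = 128, p: float = 1.0, q: float = 1.0,
             walks_per_node: int = 10, walk_length: int = 80,
             window: int = 5, negatives: int = 5, epochs: int = 1,
             seed: Optional[int] = None) -> EmbeddingMatrix:
    """node2vec: second-order biased walks + SGNS."""
    if d < 1:
        raise ValidationError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    corpus = node2vec_walks(g, p=p, q=q, walks_per_node=walks_per_node,
                            walk_length=walk_length,
                            seed=int(rng.integers(2 ** 31)))
    return _train_from_corpus(g, corpus, d, window, negatives, epochs, rng,
                              method="node2vec",
                              params={"p": p, "q": q,
                                      "walks_per_node": walks_per_node,
                                      "walk_length": walk_length,
                                      "window": window, "seed": seed})


def _train_from_corpus(g, corpus, d, window, negatives, epochs, rng,
                       method, params) -> EmbeddingMatrix:
    node_order = tuple(g.nodes)
    index = {v: i for i, v in enumerate(node_order)}
    pairs, counts = _pairs_from_walks(corpus, index, window)
    W = _sgns_train(pairs, len(node_order), d, negatives, epochs, counts,
                    rng)
    return EmbeddingMatrix(node_order=node_order, vectors=W, d=d,
                           method=method, params=params)


# ---------------------------------------------------------------------------
# LINE


def line(g: Graph, d: int = 128, order: str = "2", samples: int = 100_000,
         negatives: int = 5, seed: Optional[int] = None,
         lr0: float = 0.025) -> EmbeddingMatrix:
    """LINE: edge-sampling SGD on first- and/or second-order proximity.

    ``order`` is "1", "2" or "both"; "both" trains two independent d/2
    halves and concatenates them (*d* must then be even).  Edges are
    drawn with probability proportional to weight through an alias
    table; undirected edges are used in both orientations.
    """
    if order not in ("1", "2", "both", 1, 2):
        raise ValidationError("order must be '1', '2' or 'both'")
    order = str(order)
    if order == "both" and d % 2 != 0:
        raise ValidationError("order='both' needs an even dimension")
    if d < 1:
        raise ValidationError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    node_order = tuple(g.nodes)
    index = {v: i for i, v in enumerate(node_order)}
    n = len(node_order)
    edges = []
    weights = []
    for u, v, data in g.edges():
        edges.append((index[u], index[v]))
        weights.append(data["weight"])
        if not g.directed:
            edges.append((index[v], index[u]))
            weights.append(data["weight"])
    deg = np.zeros(n)
    for (u, v), w in zip(edges, weights):
        deg[u] += w

    def train(dd: int, second: bool) -> np.ndarray:
        trainable = deg > 0
        W = _init_vectors(n, dd, rng, trainable)
        C = np.zeros((n, dd)) if second else W
        if not edges:
            return W
        edge_alias = AliasTable(weights)
        noise = deg ** 0.75
        node_alias = AliasTable(noise)
        for step in range(samples):
            lr = max(lr0 * (1.0 - step / max(samples, 1)), lr0 * 1e-2)
            u, v = edges[edge_alias.draw(rng)]
            negs = node_alias.draw_many(rng, negatives)
            targets = np.concatenate(([v], negs))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            wu = W[u].copy()
            cv = C[targets]
            score = _sigmoid(cv @ wu)
            gradc = (score - labels)[:, None] * wu[None, :]
            gradw = (score - labels) @ cv
            C[targets] -= lr * gradc
            W[u] -= lr * gradw
        return W

    if order == "1":
        W = train(d, second=False)
    elif order == "2":
        W = train(d, second=True)
    else:
        W = np.concatenate([train(d // 2, second=False),
                            train(d // 2, second=True)], axis=1)
    return EmbeddingMatrix(node_order=node_order, vectors=W, d=d,
                           method="line",
                           params={"order": order, "samples": samples,
                                   "seed": seed})


def clique_separation(emb: EmbeddingMatrix, groups: Sequence[set]) -> float:
    """Mean intra-group cosine minus mean inter-group cosine.

    Positive values mean the embedding separates the groups.
    """
    intra, inter = [], []
    nodes = [v for grp in groups for v in grp]
    gid = {}
    for i, grp in enumerate(groups):
        for v in grp:
            gid[v] = i
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            c = emb.cosine(u, v)
            (intra if gid[u] == gid[v] else inter).append(c)
    if not intra or not inter:
        raise ValidationError("need at least two non-empty groups")
    return float(np.mean(intra) - np.mean(inter))
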