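"""Seeded synthetic-graph generation and deterministic fixtures.

Every algorithm in the toolkit is testable without downloads: the
Erdős–Rényi G(n, m) generator reproduces benchmark-style random networks
at any printed (n, m) size, and the fixture zoo provides the small
structured graphs (star, path, cliques joined by a broker, the Zachary
karate club) that the structural-hole detectors are exercised on.

All randomness flows through a single integer seed; identical seeds give
identical graphs.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional, Union

import numpy as np

from .exceptions import ValidationError
from .graph import Graph

__all__ = ["erdos_renyi_gnm", "erdos_renyi_gnp", "fixture", "karate_club",
    "two_cliques_bridge", "random_weighted"]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def erdos_renyi_gnm(n: int, m: int, directed: bool = False,
                    seed: RngLike = None) -> Graph:
    """G(n, m): exactly *m* distinct edges sampled uniformly, no self-loops.

    Node labels are 0..n-1.  Raises if *m* exceeds the maximum edge count
    for (n, directed).
    """
    if n < 0 or m < 0:
        raise ValidationError("n and m must be nonnegative")
    max_m = n * (n - 1) if directed else n * (n - 1) // 2
    if m > max_m:
        raise ValidationError(f"m={m} exceeds maximum {max_m} for n={n}")
    rng = _rng(seed)
    g = Graph(directed=directed)
    for v in range(n):
        g.add_node(v)
    # dense regime: enumerate and choose; sparse regime: rejection sample
    if max_m and m > max_m // 2 and n <= 4000:
        pairs = ([(u, v) for u in range(n) for v in range(n) if u != v]
                 if directed else
                 [(u, v) for u in range(n) for v in range(u + 1, n)])
        idx = rng.choice(len(pairs), size=m, replace=False)
        for i in sorted(idx):
            u, v = pairs[i]
            g.add_edge(u, v)
        return g
    chosen: set = set()
    while len(chosen) < m:
        k = m - len(chosen)
        us = rng.integers(0, n, size=2 * k + 8)
        vs = rng.integers(0, n, size=2 * k + 8)
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v:
                continue
            key = (u, v) if directed or u < v else (v, u)
            if key not in chosen:
                chosen.add(key)
                g.add_edge(*key)
                if len(chosen) == m:
                    break
    return g


def erdos_renyi_gnp(n: int, p: float, directed: bool = False,
                    seed: RngLike = None) -> Graph:
    """G(n, p): each possible edge present independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must be in [0, 1]")
    rng = _rng(seed)
    g = Graph(directed=directed)
    for v in range(n):
        g.add_node(v)
    for u in range(n):
        start = 0 if directed else u + 1
        for v in range(start, n):
            if u == v:
                continue
            if rng.random() < p:
                g.add_edge(u, v)
    return g


def random_weighted(n: int, m: int, directed: bool = False,
                    low: float = 0.5, high: float = 3.0,
                    seed: RngLike = None) -> Graph:
    """G(n, m) with i.i.d. uniform edge weights in [low, high]."""
    rng = _rng(seed)
    g = erdos_renyi_gnm(n, m, directed=directed, seed=rng)
    for u, v, data in g.edges():
        data["weight"] = float(rng.uniform(low, high))
    return g


def two_cliques_bridge(k: int) -> Graph:
    """Two k-cliques joined through a single broker node.

    Nodes 0..k-1 form clique A, nodes k..2k-1 form clique B, and node 2k
    (the broker) is adjacent to node 0 and node k only.  The broker is the
    unique structural-hole spanner by construction.
    """
    if k < 2:
        raise ValidationError("clique size must be at least 2")
    g = Graph()
    for i in range(k):
        for j in range(i + 1, k):
            g.add_edge(i, j)
            g.add_edge(k + i, k + j)
    broker = 2 * k
    g.add_edge(broker, 0)
    g.add_edge(broker, k)
    return g


def karate_club() -> Graph:
    """Zachary's karate-club network: 34 nodes, 78 undirected edges.

    Bundled as a native-JSON data file; node labels are 0..33.
    """
    from .io import _graph_from_native  # local import avoids a cycle
    text = resources.files("holenet.data").joinpath(
        "karate_club.json").read_text()
    return _graph_from_native(json.loads(text))


def fixture(name: str, **params) -> Graph:
    """Return a named deterministic fixture graph.

    Names: ``star`` (leaves=k), ``path`` (n), ``cycle`` (n), ``complete``
    (n), ``two_cliques_bridge`` (k), ``karate_club``.
    """
    if name == "star":
        leaves = int(params.get("leaves", 3))
        g = Graph()
        g.add_node(0)
        for i in range(1, leaves + 1):
            g.add_edge(0, i)
        return g
    if name == "path":
        n = int(params.get("n", 3))
        g = Graph()
        g.add_node(0)
        for i in range(n - 1):
            g.add_edge(i, i + 1)
        return g
    if name == "cycle":
        n = int(params.get("n", 3))
        g = Graph()
        for i in range(n):
            g.add_edge(i, (i + 1) % n)
        return g
    if name == "complete":
        n = int(params.get("n", 3))
        g = Graph()
        g.add_node(0)
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(i, j)
        return g
    if name == "two_cliques_bridge":
        return two_cliques_bridge(int(params.get("k", 4)))
    if name == "karate_club":
        return karate_club()
    raise ValidationError(f"unknown fixture {name!r}")
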