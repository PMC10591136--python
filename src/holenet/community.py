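"""Community detection: Girvan–Newman, label propagation, modularity.

Partitions produced here feed the structural-hole spanner detectors,
which need to know which groups a broker might bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .exceptions import UndefinedStatisticError, ValidationError
from .graph import Graph
from .metrics import connected_components, edge_betweenness_centrality

__all__ = ["CommunityPartition", "modularity", "girvan_newman",
           "best_girvan_newman", "label_propagation"]


@dataclass
class CommunityPartition:
    """Disjoint node blocks covering the graph, with their modularity."""

    blocks: list
    modularity: Optional[float] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.blocks = [set(b) for b in self.blocks]
        seen: set = set()
        for b in self.blocks:
            if seen & b:
                raise ValidationError("partition blocks overlap")
            seen |= b

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[set]:
        return iter(self.blocks)

    def block_of(self) -> dict:
        """Map node -> block index."""
        out = {}
        for i, b in enumerate(self.blocks):
            for v in b:
                out[v] = i
        return out

    def covers(self, g: Graph) -> bool:
        return set().union(*self.blocks) == set(g.nodes) if self.blocks \
            else g.n_nodes == 0


def modularity(g: Graph, partition: CommunityPartition) -> float:
    """Newman–Girvan modularity Q = sum_c [L_c/m - (D_c/2m)^2].

    L_c is the (weighted) intra-block edge mass and D_c the total
    (weighted) degree of block c.  Requires at least one edge.
    """
    if not partition.covers(g):
        raise ValidationError("partition does not cover the graph")
    m = sum(d["weight"] for _, _, d in g.edges())
    if m == 0:
        raise UndefinedStatisticError("modularity of an edgeless graph")
    block = partition.block_of()
    L = [0.0] * len(partition.blocks)
    D = [0.0] * len(partition.blocks)
    for u, v, data in g.edges():
        w = data["weight"]
        if block[u] == block[v]:
            L[block[u]] += w
        D[block[u]] += w
        D[block[v]] += w
    return sum(L[c] / m - (D[c] / (2.0 * m)) ** 2
               for c in range(len(partition.blocks)))


def _component_partition(g: Graph) -> CommunityPartition:
    return CommunityPartition(blocks=connected_components(g))


def girvan_newman(g: Graph):
    """Yield the component partition after each highest-betweenness
    edge removal (deterministic tie-break on endpoint labels).

    The first yield is the starting component partition; the sequence
    ends when no edges remain.  Works on a private copy of *g*.
    """
    if g.directed:
        raise ValidationError("Girvan–Newman expects an undirected graph")
    if g.n_nodes == 0:
        raise ValidationError("empty graph")
    work = g.copy()
    part = _component_partition(work)
    part.modularity = modularity(g, part) if g.n_edges else None
    yield part
    while work.n_edges > 0:
        ebc = edge_betweenness_centrality(work)
        # tie-break: highest score, then lexicographically smallest edge
        top = max(ebc.values())
        candidates = [e for e, x in ebc.items() if abs(x - top) <= 1e-12]
        best = min(candidates, key=lambda e: (str(e[0]), str(e[1])))
        work.remove_edge(*best)
        part = _component_partition(work)
        part.modularity = modularity(g, part)
        yield part


def best_girvan_newman(g: Graph) -> CommunityPartition:
    """The yielded partition with maximal modularity (first on ties)."""
    best = None
    for part in girvan_newman(g):
        if part.modularity is None:
            continue
        if best is None or part.modularity > best.modularity + 1e-12:
            best = part
    if best is None:
        raise UndefinedStatisticError("no partition for an edgeless graph")
    return best


def label_propagation(g: Graph, seed: Optional[int] = None,
                      max_sweeps: int = 100) -> CommunityPartition:
    """Asynchronous label propagation with a seeded update order.

    Each node adopts the plurality label among its neighbors (both
    directions in directed graphs); ties are broken by a seeded draw.
    Stops when a full sweep changes nothing.  Deterministic given *seed*.
    """
    if g.n_nodes == 0:
        raise ValidationError("empty graph")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    labels = {v: i for i, v in enumerate(nodes)}
    if g.directed:
        und = {v: list({**g.adj[v], **g.pred[v]}) for v in nodes}
    else:
        und = {v: [u for u in g.adj[v] if u != v] for v in nodes}
    for _ in range(max_sweeps):
        order = list(nodes)
        rng.shuffle(order)
        changed = False
        for v in order:
            if not und[v]:
                continue
            counts: dict = {}
            for u in und[v]:
                counts[labels[u]] = counts.get(labels[u], 0) + 1
            top = max(counts.values())
            winners = sorted(lab for lab, c in counts.items() if c == top)
            choice = winners[int(rng.integers(len(winners)))]
            if choice != labels[v]:
                labels[v] = choice
                changed = True
        if not changed:
            break
    groups: dict = {}
    for v in nodes:
        groups.setdefault(labels[v], set()).add(v)
    part = CommunityPartition(blocks=list(groups.values()),
                              params={"seed": seed})
    part.modularity = modularity(g, part) if g.n_edges else None
    return part
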