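"""Shortest paths, centralities, k-core, clustering and triangles.

Conventions used throughout:

* Unreachable distances are ``math.inf``, never a numeric overflow value.
* Closeness follows the component-wise convention score(v) =
  (r - 1) / sum of distances to the r - 1 other reachable nodes, so
  disconnected graphs still get meaningful per-component scores.
* Betweenness is Brandes' dependency accumulation; unnormalized by
  default, with each unordered pair counted once on undirected graphs.
  A ``sources`` list restricts accumulation to those sources (the
  sampled mode used when benchmarking very large networks).
* ``k_core`` is the Matula–Beck peeling with an O(n + m) bucket ordering
  of degrees; ``multi_source_dijkstra`` uses an indexed binary heap with
  O(log n) decrease-key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

from .exceptions import CapabilityError, ValidationError
from .graph import Graph

__all__ = [
    "DistanceMap", "CentralityTable", "CoreTable",
    "multi_source_dijkstra", "single_source_shortest_paths",
    "betweenness_centrality", "edge_betweenness_centrality",
    "closeness_centrality", "pagerank", "k_core",
    "local_clustering", "average_clustering", "triangle_count",
    "degree_centrality", "connected_components", "articulation_points",
    "diameter",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DistanceMap:
    """Distances from a source set; ``dist[v] = inf`` when unreachable."""

    sources: frozenset
    dist: dict
    pred: Optional[dict] = None

    def __getitem__(self, v):
        return self.dist[v]


@dataclass
class CentralityTable:
    """Per-node scores for one centrality metric."""

    metric: str
    scores: dict
    normalized: bool = False
    sampled_sources: Optional[tuple] = None

    def __getitem__(self, v):
        return self.scores[v]

    def __iter__(self):
        return iter(self.scores)

    def items(self):
        return self.scores.items()

    def top(self, k: int) -> list:
        """k best-scoring nodes, ties broken by label string order."""
        return sorted(self.scores, key=lambda v: (-self.scores[v], str(v)))[:k]


@dataclass
class CoreTable:
    """Per-node core numbers."""

    core: dict

    def __getitem__(self, v):
        return self.core[v]

    def items(self):
        return self.core.items()


# ---------------------------------------------------------------------------
# indexed binary heap (decrease-key priority structure for Dijkstra)


class _IndexedHeap:
    """Binary min-heap keyed by node with O(log n) decrease-key."""

    __slots__ = ("_heap", "_pos", "_key")

    def __init__(self):
        self._heap: list = []   # entries [key, node]
        self._pos: dict = {}

    def __len__(self):
        return len(self._heap)

    def __contains__(self, node):
        return node in self._pos

    def push(self, node, key):
        if node in self._pos:
            self.decrease(node, key)
            return
        self._heap.append([key, node])
        self._pos[node] = len(self._heap) - 1
        self._sift_up(len(self._heap) - 1)

    def decrease(self, node, key):
        i = self._pos[node]
        if key < self._heap[i][0]:
            self._heap[i][0] = key
            self._sift_up(i)

    def pop(self):
        heap, pos = self._heap, self._pos
        top = heap[0]
        last = heap.pop()
        del pos[top[1]]
        if heap:
            heap[0] = last
            pos[last[1]] = 0
            self._sift_down(0)
        return top[1], top[0]

    def _sift_up(self, i):
        heap, pos = self._heap, self._pos
        item = heap[i]
        while i > 0:
            parent = (i - 1) >> 1
            if heap[parent][0] <= item[0]:
                break
            heap[i] = heap[parent]
            pos[heap[i][1]] = i
            i = parent
        heap[i] = item
        pos[item[1]] = i

    def _sift_down(self, i):
        heap, pos = self._heap, self._pos
        n = len(heap)
        item = heap[i]
        while True:
            child = 2 * i + 1
            if child >= n:
                break
            if child + 1 < n and heap[child + 1][0] < heap[child][0]:
                child += 1
            if heap[child][0] >= item[0]:
                break
            heap[i] = heap[child]
            pos[heap[i][1]] = i
            i = child
        heap[i] = item
        pos[item[1]] = i


# ---------------------------------------------------------------------------
# shortest paths


def multi_source_dijkstra(g: Graph, sources: Iterable[Hashable],
                          weighted: bool = True,
                          with_pred: bool = False) -> DistanceMap:
    """Minimum distance from any source to every node.

    With ``weighted=False`` every edge counts 1 regardless of stored
    weight.  All weights must be positive when weighted.
    """
    src = list(sources)
    if not src:
        raise ValidationError("sources must be nonempty")
    for s in src:
        if s not in g:
            raise KeyError(f"source {s!r} not in graph")
    if weighted:
        for _, _, data in g.edges():
            if data["weight"] <= 0:
                raise ValidationError("Dijkstra requires positive weights")
    dist = {v: math.inf for v in g.nodes}
    pred: Optional[dict] = {v: set() for v in g.nodes} if with_pred else None
    heap = _IndexedHeap()
    for s in src:
        dist[s] = 0.0
        heap.push(s, 0.0)
    done = set()
    while len(heap):
        u, d = heap.pop()
        if u in done:
            continue
        done.add(u)
        for v, data in g.adj[u].items():
            w = data["weight"] if weighted else 1.0
            nd = d + w
            if nd < dist[v] - 1e-15 * max(1.0, abs(nd)):
                dist[v] = nd
                heap.push(v, nd)
                if with_pred:
                    pred[v] = {u}
            elif with_pred and math.isclose(nd, dist[v], rel_tol=1e-12):
                pred[v].add(u)
    return DistanceMap(sources=frozenset(src), dist=dist, pred=pred)


def single_source_shortest_paths(g: Graph, s: Hashable,
                                 weighted: bool = False) -> DistanceMap:
    return multi_source_dijkstra(g, [s], weighted=weighted)


def _bfs_dist(adj, s) -> dict:
    dist = {s: 0}
    queue = [s]
    for u in queue:
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def diameter(g: Graph) -> int:
    """Longest shortest path (hop count); inf if disconnected."""
    best = 0
    for s in g.nodes:
        dist = _bfs_dist(g.adj, s)
        if len(dist) < g.n_nodes:
            return math.inf
        best = max(best, max(dist.values()))
    return best


# ---------------------------------------------------------------------------
# betweenness (Brandes 2001)


def _brandes_sssp(g: Graph, s, weighted: bool):
    """Order of settlement, predecessor DAG and path counts from s."""
    sigma = {v: 0.0 for v in g.nodes}
    pred = {v: [] for v in g.nodes}
    sigma[s] = 1.0
    order = []
    if not weighted:
        dist = {v: -1 for v in g.nodes}
        dist[s] = 0
        queue = [s]
        for u in queue:
            order.append(u)
            for v in g.adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
        return order, pred, sigma
    dist = {v: math.inf for v in g.nodes}
    dist[s] = 0.0
    heap = _IndexedHeap()
    heap.push(s, 0.0)
    done = set()
    while len(heap):
        u, d = heap.pop()
        if u in done:
            continue
        done.add(u)
        order.append(u)
        for v, data in g.adj[u].items():
            nd = d + data["weight"]
            if nd < dist[v] - 1e-12 * max(1.0, abs(nd)):
                dist[v] = nd
                heap.push(v, nd)
                sigma[v] = sigma[u]
                pred[v] = [u]
            elif math.isclose(nd, dist[v], rel_tol=1e-12):
                sigma[v] += sigma[u]
                pred[v].append(u)
    return order, pred, sigma


def brandes_partial(g: Graph, sources: Sequence, weighted: bool = False,
                    edges: bool = False) -> dict:
    """Dependency accumulation restricted to the given source nodes.

    Returns raw directed-sense sums; callers halve for undirected graphs.
    Used both by :func:`betweenness_centrality` and the parallel layer.
    """
    if edges:
        acc: dict = {}
        for u, v, _ in g.edges():
            acc[(u, v)] = 0.0
    else:
        acc = {v: 0.0 for v in g.nodes}
    for s in sources:
        order, pred, sigma = _brandes_sssp(g, s, weighted)
        delta = {v: 0.0 for v in g.nodes}
        for w in reversed(order):
            for u in pred[w]:
                c = sigma[u] / sigma[w] * (1.0 + delta[w])
                if edges:
                    key = (u, w) if (u, w) in acc else (w, u)
                    acc[key] += c
                delta[u] += c
            if w != s and not edges:
                acc[w] += delta[w]
    return acc


def betweenness_centrality(g: Graph, normalized: bool = False,
                           sources: Optional[Sequence] = None,
                           weighted: bool = False) -> CentralityTable:
    """Brandes betweenness; each unordered pair counted once (undirected)."""
    if g.n_nodes == 0:
        raise ValidationError("betweenness of an empty graph")
    src = list(g.nodes) if sources is None else list(sources)
    acc = brandes_partial(g, src, weighted=weighted)
    if not g.directed:
        acc = {v: x / 2.0 for v, x in acc.items()}
    if normalized:
        n = g.n_nodes
        denom = ((n - 1) * (n - 2) / 2.0 if not g.directed
                 else float((n - 1) * (n - 2)))
        if denom > 0:
            acc = {v: x / denom for v, x in acc.items()}
    return CentralityTable(
        metric="betweenness", scores=acc, normalized=normalized,
        sampled_sources=None if sources is None else tuple(src))


def edge_betweenness_centrality(g: Graph,
                                weighted: bool = False) -> dict:
    """Per-edge Brandes betweenness, keyed by stored edge orientation."""
    acc = brandes_partial(g, list(g.nodes), weighted=weighted, edges=True)
    if not g.directed:
        acc = {e: x / 2.0 for e, x in acc.items()}
    return acc


# ---------------------------------------------------------------------------
# closeness, degree, pagerank


def closeness_centrality(g: Graph,
                         sources: Optional[Sequence] = None) -> CentralityTable:
    """Component-wise closeness (r-1)/sum(d); isolated nodes score 0."""
    nodes = list(g.nodes) if sources is None else list(sources)
    scores = {}
    for v in nodes:
        dist = _bfs_dist(g.adj, v)
        r = len(dist)
        total = sum(dist.values())
        scores[v] = (r - 1) / total if total > 0 else 0.0
    return CentralityTable(
        metric="closeness", scores=scores,
        sampled_sources=None if sources is None else tuple(nodes))


def degree_centrality(g: Graph, mode: str = "total") -> CentralityTable:
    n = g.n_nodes
    denom = max(n - 1, 1)
    scores = {v: g.degree(v, mode) / denom for v in g.nodes}
    return CentralityTable(metric="degree", scores=scores, normalized=True)


def pagerank(g: Graph, damping: float = 0.85, tol: float = 1e-8,
             max_iter: int = 200, weighted: bool = False) -> CentralityTable:
    """Power iteration with uniform teleport and uniform dangling mass.

    Scores sum to 1.  Emits a RuntimeWarning and returns the best iterate
    when the L1 change has not dropped below *tol* within *max_iter*.
    """
    if not 0.0 < damping < 1.0:
        raise ValidationError("damping must be in (0, 1)")
    n = g.n_nodes
    if n == 0:
        raise ValidationError("pagerank of an empty graph")
    nodes = list(g.nodes)
    x = {v: 1.0 / n for v in nodes}
    out_mass = {}
    for v in nodes:
        if weighted:
            out_mass[v] = sum(d["weight"] for d in g.adj[v].values())
        else:
            out_mass[v] = float(len(g.adj[v]))
    converged = False
    for _ in range(max_iter):
        nxt = {v: 0.0 for v in nodes}
        dangling = sum(x[v] for v in nodes if out_mass[v] == 0.0)
        for v in nodes:
            if out_mass[v] == 0.0:
                continue
            share = x[v] / out_mass[v]
            for u, data in g.adj[v].items():
                nxt[u] += share * (data["weight"] if weighted else 1.0)
        base = (1.0 - damping) / n + damping * dangling / n
        nxt = {v: base + damping * nxt[v] for v in nodes}
        err = sum(abs(nxt[v] - x[v]) for v in nodes)
        x = nxt
        if err < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn(f"pagerank did not converge in {max_iter} iterations",
                      RuntimeWarning)
    return CentralityTable(metric="pagerank", scores=x, normalized=True)


# ---------------------------------------------------------------------------
# k-core (Matula–Beck bucket peeling)


def k_core(g: Graph) -> CoreTable:
    """Core number of every node via linear-time bucket peeling.

    Directed graphs are peeled on total degree; self-loops are ignored.
    """
    deg = {}
    adj = {}
    for v in g.nodes:
        if g.directed:
            nbrs = set(g.adj[v]) | set(g.pred[v])
        else:
            nbrs = set(g.adj[v])
        nbrs.discard(v)
        adj[v] = nbrs
        deg[v] = len(nbrs) if not g.directed else (
            sum(1 for u in g.adj[v] if u != v)
            + sum(1 for u in g.pred[v] if u != v))
    if not deg:
        return CoreTable(core={})
    # bucket sort nodes by degree: O(n + m) ordering
    max_deg = max(deg.values())
    buckets: list[list] = [[] for _ in range(max_deg + 1)]
    for v, d in deg.items():
        buckets[d].append(v)
    order = [v for bucket in buckets for v in bucket]
    pos = {v: i for i, v in enumerate(order)}
    bucket_start = [0] * (max_deg + 2)
    for d in range(1, max_deg + 1):
        bucket_start[d] = bucket_start[d - 1] + len(buckets[d - 1])
    cur = dict(deg)
    core = {}
    for i in range(len(order)):
        v = order[i]
        core[v] = cur[v]
        for u in adj[v]:
            if u in core:
                continue
            # a directed neighbor may lose two arcs (u->v and v->u)
            arcs = 1 if not g.directed else (
                (1 if u in g.adj[v] else 0) + (1 if v in g.adj[u] else 0))
            for _ in range(arcs):
                if cur[u] <= cur[v]:
                    break
                # swap u to the front of its bucket, then shrink the bucket
                du = cur[u]
                pu, pw = pos[u], bucket_start[du]
                w = order[pw]
                order[pu], order[pw] = w, u
                pos[u], pos[w] = pw, pu
                bucket_start[du] += 1
                cur[u] -= 1
    return CoreTable(core=core)


# ---------------------------------------------------------------------------
# clustering and triangles


def _undirected_neighbor_sets(g: Graph) -> dict:
    nbrs = {}
    for v in g.nodes:
        s = set(g.adj[v])
        if g.directed:
            s |= set(g.pred[v])
        s.discard(v)
        nbrs[v] = s
    return nbrs


def local_clustering(g: Graph, v: Hashable) -> float:
    """Fraction of neighbor pairs of v that are themselves linked."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    nbrs = _undirected_neighbor_sets(g)
    nv = nbrs[v]
    k = len(nv)
    if k < 2:
        return 0.0
    links = 0
    for u in nv:
        links += len(nbrs[u] & nv)
    return links / (k * (k - 1))


def average_clustering(g: Graph) -> float:
    if g.n_nodes == 0:
        raise ValidationError("clustering of an empty graph")
    return sum(local_clustering(g, v) for v in g.nodes) / g.n_nodes


def triangle_count(g: Graph) -> int:
    """Number of distinct 3-cliques in an undirected graph."""
    if g.directed:
        raise CapabilityError("triangle counting is defined here for "
                              "undirected graphs only")
    nbrs = _undirected_neighbor_sets(g)
    count = 0
    index = {v: i for i, v in enumerate(g.nodes)}
    for v in g.nodes:
        for u in nbrs[v]:
            if index[u] <= index[v]:
                continue
            for w in nbrs[v] & nbrs[u]:
                if index[w] > index[u]:
                    count += 1
    return count


# ---------------------------------------------------------------------------
# components and articulation points


def connected_components(g: Graph) -> list[set]:
    """Weakly connected components, in first-seen node order."""
    seen = set()
    comps = []
    if g.directed:
        und = {v: set(g.adj[v]) | set(g.pred[v]) for v in g.nodes}
    else:
        und = g.adj
    for s in g.nodes:
        if s in seen:
            continue
        comp = {s}
        queue = [s]
        for u in queue:
            for v in und[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def articulation_points(g: Graph) -> set:
    """Cut vertices of the undirected view, via iterative low-link DFS."""
    adj = g.adj if not g.directed else {
        v: {**g.adj[v], **g.pred[v]} for v in g.nodes}
    visited = set()
    points = set()
    for root in g.nodes:
        if root in visited:
            continue
        disc = {root: 0}
        low = {root: 0}
        parent = {root: None}
        visited.add(root)
        root_children = 0
        stack = [(root, iter(adj[root]))]
        counter = 1
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if w == v:
                    continue
                if w not in disc:
                    disc[w] = low[w] = counter
                    counter += 1
                    parent[w] = v
                    visited.add(w)
                    if v == root:
                        root_children += 1
                    stack.append((w, iter(adj[w])))
                    advanced = True
                    break
                elif w != parent[v]:
                    low[v] = min(low[v], disc[w])
            if not advanced:
                stack.pop()
                if stack:
                    p = stack[-1][0]
                    low[p] = min(low[p], low[v])
                    if p != root and low[v] >= disc[p]:
                        points.add(p)
        if root_children > 1:
            points.add(root)
    return points
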