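"""Mutable graph data model with cached-view ("dirty flag") semantics.

The :class:`Graph` stores a simple directed or undirected graph over
arbitrary hashable node labels, with per-node and per-edge attribute maps
and positive edge weights.  Every mutation bumps an internal version
counter; :class:`CachedView` snapshots (fixed node order, degree table,
compact CSR adjacency) carry the version they were built against and
rebuild themselves transparently when queried after a mutation.  This is
the dirty-flag pattern: derived state is recomputed only when the
underlying variables have actually changed.

Performance contracts: edge insert/remove are O(1) amortized dict
operations, neighbor iteration is O(deg), and a view rebuild is O(n + m).
"""

from __future__ import annotations

from typing import Any, Hashable, Iterable, Iterator, Optional

import numpy as np

from .exceptions import UndefinedStatisticError, ValidationError

__all__ = ["Graph", "DiGraph", "CachedView", "average_degree", "density"]


class Graph:
    """A simple (no parallel edges) weighted graph with attribute storage.

    Parameters
    ----------
    directed:
        Whether edges are ordered pairs.  Undirected adjacency is kept
        symmetric: the edge-data dict is shared between ``adj[u][v]`` and
        ``adj[v][u]``.
    """

    def __init__(self, directed: bool = False):
        self._directed = bool(directed)
        self._node: dict[Hashable, dict[str, Any]] = {}
        self._adj: dict[Hashable, dict[Hashable, dict[str, Any]]] = {}
        # predecessor adjacency, only maintained for directed graphs
        self._pred: Optional[dict] = {} if self._directed else None
        self._m = 0
        self._version = 0
        self._view: Optional[CachedView] = None

    # -- basic properties -------------------------------------------------

    @property
    def directed(self) -> bool:
        return self._directed

    @property
    def n_nodes(self) -> int:
        return len(self._node)

    @property
    def n_edges(self) -> int:
        return self._m

    def __len__(self) -> int:
        return len(self._node)

    def __contains__(self, v: Hashable) -> bool:
        return v in self._node

    def __iter__(self) -> Iterator[Hashable]:
        return iter(self._node)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self._directed else "undirected"
        return f"<{type(self).__name__} {kind} n={self.n_nodes} m={self.n_edges}>"

    # -- mutation ---------------------------------------------------------

    def _touch(self) -> None:
        self._version += 1

    def add_node(self, v: Hashable, **attrs: Any) -> None:
        if v not in self._node:
            self._node[v] = {}
            self._adj[v] = {}
            if self._directed:
                self._pred[v] = {}
        if attrs:
            self._node[v].update(attrs)
        self._touch()

    def add_edge(self, u: Hashable, v: Hashable, weight: float = 1.0,
                 **attrs: Any) -> None:
        """Insert (or overwrite) the edge u-v.

        Endpoints are auto-created.  Re-adding an existing edge overwrites
        its weight and attributes; the edge count does not change.
        """
        weight = float(weight)
        if weight <= 0:
            raise ValidationError(f"edge weight must be positive, got {weight}")
        for x in (u, v):
            if x not in self._node:
                self._node[x] = {}
                self._adj[x] = {}
                if self._directed:
                    self._pred[x] = {}
        new = v not in self._adj[u]
        data = self._adj[u].get(v)
        if data is None:
            data = {}
        data["weight"] = weight
        data.update(attrs)
        self._adj[u][v] = data
        if self._directed:
            self._pred[v][u] = data
        else:
            self._adj[v][u] = data
        if new:
            self._m += 1
        self._touch()

    def add_edges_from(self, edges: Iterable) -> None:
        for e in edges:
            if len(e) == 2:
                self.add_edge(e[0], e[1])
            else:
                self.add_edge(e[0], e[1], weight=e[2])

    def remove_edge(self, u: Hashable, v: Hashable) -> None:
        if u not in self._adj or v not in self._adj[u]:
            raise KeyError(f"edge ({u!r}, {v!r}) not in graph")
        del self._adj[u][v]
        if self._directed:
            del self._pred[v][u]
        elif u != v:
            del self._adj[v][u]
        self._m -= 1
        self._touch()

    def remove_node(self, v: Hashable) -> None:
        if v not in self._node:
            raise KeyError(f"node {v!r} not in graph")
        if self._directed:
            for u in list(self._adj[v]):
                del self._pred[u][v]
                self._m -= 1
            for u in list(self._pred[v]):
                if u != v:
                    del self._adj[u][v]
                    self._m -= 1
            del self._pred[v]
        else:
            for u in list(self._adj[v]):
                if u != v:
                    del self._adj[u][v]
                self._m -= 1
        del self._adj[v]
        del self._node[v]
        self._touch()

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self):
        return self._node

    def node_attrs(self, v: Hashable) -> dict:
        return self._node[v]

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        return u in self._adj and v in self._adj[u]

    def edge_data(self, u: Hashable, v: Hashable) -> dict:
        return self._adj[u][v]

    def weight(self, u: Hashable, v: Hashable, default: float = 0.0) -> float:
        """Edge weight of u->v, or *default* when the edge is absent."""
        try:
            return self._adj[u][v]["weight"]
        except KeyError:
            return default

    @property
    def adj(self):
        return self._adj

    @property
    def pred(self):
        if not self._directed:
            return self._adj
        return self._pred

    def neighbors(self, v: Hashable) -> Iterator[Hashable]:
        """Out-neighbors (successors) in insertion order."""
        if v not in self._adj:
            raise KeyError(f"node {v!r} not in graph")
        return iter(self._adj[v])

    def predecessors(self, v: Hashable) -> Iterator[Hashable]:
        if not self._directed:
            return self.neighbors(v)
        if v not in self._pred:
            raise KeyError(f"node {v!r} not in graph")
        return iter(self._pred[v])

    def degree(self, v: Hashable, mode: str = "total") -> int:
        """Degree of *v*: ``in``, ``out`` or ``total``.

        For undirected graphs all modes agree; a self-loop contributes 2
        to the total degree so that the handshake identity sum(deg) = 2m
        holds.
        """
        if v not in self._node:
            raise KeyError(f"node {v!r} not in graph")
        if not self._directed:
            d = len(self._adj[v]) + (1 if v in self._adj[v] else 0)
            return d
        out = len(self._adj[v])
        inn = len(self._pred[v])
        if mode == "out":
            return out
        if mode == "in":
            return inn
        if mode == "total":
            return out + inn
        raise ValidationError(f"unknown degree mode {mode!r}")

    def edges(self):
        """Iterate (u, v, data) once per stored edge.

        Undirected edges are reported once, oriented by first insertion.
        """
        if self._directed:
            for u, nbrs in self._adj.items():
                for v, data in nbrs.items():
                    yield u, v, data
        else:
            seen = set()
            for u, nbrs in self._adj.items():
                for v, data in nbrs.items():
                    key = id(data)
                    if key in seen:
                        continue
                    seen.add(key)
                    yield u, v, data

    # -- derived structures -----------------------------------------------

    def copy(self) -> "Graph":
        g = type(self)(directed=self._directed)
        for v, a in self._node.items():
            g.add_node(v, **a)
        for u, v, data in self.edges():
            g.add_edge(u, v, **data)
        return g

    def subgraph(self, nodes: Iterable[Hashable]) -> "Graph":
        keep = set(nodes)
        missing = keep - set(self._node)
        if missing:
            raise KeyError(f"nodes not in graph: {sorted(map(repr, missing))}")
        g = type(self)(directed=self._directed)
        for v in self._node:
            if v in keep:
                g.add_node(v, **self._node[v])
        for u, v, data in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v, **data)
        return g

    def to_undirected(self) -> "Graph":
        if not self._directed:
            return self.copy()
        g = Graph(directed=False)
        for v, a in self._node.items():
            g.add_node(v, **a)
        for u, v, data in self.edges():
            g.add_edge(u, v, **data)
        return g

    def snapshot(self) -> "CachedView":
        """Return the current cached view, rebuilding only if stale."""
        if self._view is None or not self._view.valid:
            self._view = CachedView(self)
        return self._view


class DiGraph(Graph):
    """Convenience subclass: ``DiGraph()`` == ``Graph(directed=True)``."""

    def __init__(self, directed: bool = True):
        if not directed:
            raise ValidationError("DiGraph is always directed")
        super().__init__(directed=True)


class CachedView:
    """Frozen index snapshot of a :class:`Graph`.

    Holds a fixed node order, per-node in/out/total degree table and a
    compact CSR adjacency (``indptr``/``indices`` into ``node_order``).
    ``valid`` turns false as soon as the owning graph mutates; any query
    through an invalid view rebuilds it first, so results always equal a
    from-scratch construction.
    """

    def __init__(self, graph: Graph):
        self._graph = graph
        self._build()

    def _build(self) -> None:
        g = self._graph
        self.node_order: tuple = tuple(g._node)
        self.index: dict = {v: i for i, v in enumerate(self.node_order)}
        n = len(self.node_order)
        out_deg = np.zeros(n, dtype=np.int64)
        in_deg = np.zeros(n, dtype=np.int64)
        indptr = np.zeros(n + 1, dtype=np.int64)
        for i, v in enumerate(self.node_order):
            out_deg[i] = len(g._adj[v])
            indptr[i + 1] = indptr[i] + out_deg[i]
        indices = np.empty(indptr[-1], dtype=np.int64)
        weights = np.empty(indptr[-1], dtype=np.float64)
        pos = 0
        for v in self.node_order:
            for w, data in g._adj[v].items():
                indices[pos] = self.index[w]
                weights[pos] = data["weight"]
                pos += 1
        if g._directed:
            for i, v in enumerate(self.node_order):
                in_deg[i] = len(g._pred[v])
        else:
            in_deg = out_deg
        self.indptr = indptr
        self.indices = indices
        self.weights = weights
        self.in_degree = in_deg
        self.out_degree = out_deg
        if g._directed:
            self.total_degree = in_deg + out_deg
        else:
            loops = np.zeros(n, dtype=np.int64)
            for i, v in enumerate(self.node_order):
                if v in g._adj[v]:
                    loops[i] = 1
            self.total_degree = out_deg + loops
        self._built_version = g._version

    @property
    def valid(self) -> bool:
        return self._built_version == self._graph._version

    def _ensure(self) -> None:
        if not self.valid:
            self._build()

    def degree(self, v: Hashable, mode: str = "total") -> int:
        self._ensure()
        i = self.index[v]
        table = {"in": self.in_degree, "out": self.out_degree,
                 "total": self.total_degree}
        if mode not in table:
            raise ValidationError(f"unknown degree mode {mode!r}")
        return int(table[mode][i])

    def neighbors(self, v: Hashable) -> list:
        self._ensure()
        i = self.index[v]
        return [self.node_order[j]
                for j in self.indices[self.indptr[i]:self.indptr[i + 1]]]

    def degree_table(self) -> dict:
        self._ensure()
        return {v: int(self.total_degree[i])
                for i, v in enumerate(self.node_order)}


# -- whole-graph statistics ------------------------------------------------

def average_degree(g: Graph) -> float:
    """Mean total degree, 2m/n for both directed and undirected graphs.

    For a directed graph the total degree of a node is in-degree plus
    out-degree, so the mean is again 2m/n.
    """
    if g.n_nodes < 1:
        raise UndefinedStatisticError("average degree of an empty graph")
    return 2.0 * g.n_edges / g.n_nodes


def density(g: Graph) -> float:
    """Edge density: 2m/(n(n-1)) undirected, m/(n(n-1)) directed."""
    n, m = g.n_nodes, g.n_edges
    if n < 2:
        raise UndefinedStatisticError("density needs at least 2 nodes")
    if g.directed:
        return m / (n * (n - 1))
    return 2.0 * m / (n * (n - 1))
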