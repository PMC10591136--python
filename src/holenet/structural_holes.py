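"""Burt's structural-hole metrics and structural-hole spanner detection.

A structural hole is a gap between two groups that lack direct ties;
the node bridging the gap (the spanner, or broker) enjoys an
informational advantage.  This module provides

* Burt's per-node metrics — proportional tie strengths, effective size,
  efficiency, constraint and hierarchy — computed from (possibly
  weighted) adjacency exactly as in the classic formulation, and
* seven spanner detectors: the HIS two-score recurrence, MaxD
  (min-cut reduction), Greedy and AP_Greedy (shortest-path inflation on
  removal, exact everywhere vs. restricted to articulation points),
  ICC / BICC / AP_BICC (harmonic-closeness loss on removal, exact /
  radius-bounded prune / articulation-point-only), and the two WeakTie
  cross-community tie counters.

All detectors return an :class:`SHScoreTable` whose top-k ranking uses
the deterministic tie-break (score descending, then label ascending as
text), so results are reproducible and invariant under node relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Optional

from .community import CommunityPartition
from .exceptions import UndefinedStatisticError, ValidationError
from .graph import Graph
from .metrics import _bfs_dist, articulation_points

__all__ = [
    "SHScoreTable", "tie_strengths", "effective_size", "efficiency",
    "constraint", "hierarchy",
    "detect_his", "detect_maxd", "detect_greedy", "detect_ap_greedy",
    "detect_icc", "detect_bicc", "detect_ap_bicc", "detect_weak_tie",
]


@dataclass
class SHScoreTable:
    """Per-node structural-hole scores with a ranked top-k selection."""

    method: str
    scores: dict
    top: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __getitem__(self, v):
        return self.scores[v]

    def items(self):
        return self.scores.items()


def _topk(scores: dict, k: int) -> list:
    return sorted(scores, key=lambda v: (-scores[v], str(v)))[:k]


def _check_k(g: Graph, k: int) -> None:
    if k < 0 or k >= g.n_nodes:
        raise ValidationError(f"k={k} must satisfy 0 <= k < n={g.n_nodes}")


# ---------------------------------------------------------------------------
# Burt metrics


def _sym_weight(g: Graph, u, v) -> float:
    """z_uv + z_vu for directed graphs; the edge weight for undirected."""
    if g.directed:
        return g.weight(u, v, 0.0) + g.weight(v, u, 0.0)
    return g.weight(u, v, 0.0)


def _contacts(g: Graph, v) -> list:
    """Neighbors in either direction, excluding v itself."""
    if g.directed:
        seen = dict.fromkeys(list(g.adj[v]) + list(g.pred[v]))
    else:
        seen = dict.fromkeys(g.adj[v])
    seen.pop(v, None)
    return list(seen)


def tie_strengths(g: Graph, i: Hashable) -> dict:
    """Proportional tie strength p_ij = (z_ij + z_ji) / sum_k (z_ik + z_ki).

    Sums to 1 over the contacts of any non-isolated node.
    """
    contacts = _contacts(g, i)
    total = sum(_sym_weight(g, i, j) for j in contacts)
    if total == 0:
        return {}
    return {j: _sym_weight(g, i, j) / total for j in contacts}


def effective_size(g: Graph, v: Hashable) -> float:
    """Contacts of v discounted by their redundancy with one another.

    ES(v) = sum_j [1 - sum_{q != j} p_vq * m_jq], where m_jq is j's tie
    to q scaled by j's strongest tie.  A star center keeps its full
    degree; a clique member keeps 1.
    """
    contacts = _contacts(g, v)
    if not contacts:
        raise UndefinedStatisticError(
            f"effective size of isolated node {v!r}")
    p = tie_strengths(g, v)
    total = 0.0
    for j in contacts:
        j_ties = [_sym_weight(g, j, k) for k in _contacts(g, j)]
        zmax = max(j_ties) if j_ties else 0.0
        redundancy = 0.0
        if zmax > 0:
            for q in contacts:
                if q == j:
                    continue
                redundancy += p[q] * (_sym_weight(g, j, q) / zmax)
        total += 1.0 - redundancy
    return total


def efficiency(g: Graph, v: Hashable) -> float:
    """Effective size per contact: ES(v) / deg(v), in (0, 1]."""
    contacts = _contacts(g, v)
    if not contacts:
        raise UndefinedStatisticError(f"efficiency of isolated node {v!r}")
    return effective_size(g, v) / len(contacts)


def _constraint_terms(g: Graph, v: Hashable) -> dict:
    p = tie_strengths(g, v)
    terms = {}
    for j in p:
        indirect = sum(p[q] * tie_strengths(g, q).get(j, 0.0)
                       for q in p if q != j)
        terms[j] = (p[j] + indirect) ** 2
    return terms


def constraint(g: Graph, v: Hashable) -> float:
    """Burt's constraint C_v = sum_j (p_vj + sum_q p_vq p_qj)^2.

    High constraint means v's contacts are concentrated in one
    interconnected cluster; structural-hole-rich nodes score low.
    """
    if not _contacts(g, v):
        raise UndefinedStatisticError(f"constraint of isolated node {v!r}")
    return sum(_constraint_terms(g, v).values())


def hierarchy(g: Graph, v: Hashable) -> float:
    """Concentration of constraint in a single contact, in [0, 1].

    H_v = sum_j (c_vj / (C_v/N)) ln(c_vj / (C_v/N)) / (N ln N) with
    N = deg(v); zero when the constraint is spread evenly, and defined
    as 0 for nodes with fewer than two contacts.
    """
    terms = _constraint_terms(g, v)
    N = len(terms)
    if N < 2:
        return 0.0
    C = sum(terms.values())
    if C == 0:
        return 0.0
    mean = C / N
    total = 0.0
    for c in terms.values():
        r = c / mean
        if r > 0:
            total += r * math.log(r)
    return total / (N * math.log(N))


# ---------------------------------------------------------------------------
# HIS: two mutually recursive scores over community pairs


def detect_his(g: Graph, partition: CommunityPartition, k: int = 1,
               params: Optional[dict] = None) -> SHScoreTable:
    """Bridging scores from the community-importance recurrence.

    Maintains an importance score I(v, C_i) per community and a bridging
    score H(v, S) per community pair S; iterates

        H(v, S)   = min_{i in S} I(v, C_i)
        I(v, C_i) = max(I(v, C_i),
                        max_{u ~ v, S containing i} alpha*I(u, C_i)
                                                    + beta*H(u, S))

    to a fixed point (tolerance 1e-6, at most 100 sweeps).  The final
    per-node score is the maximum bridging score over community pairs.
    ``alpha`` and ``beta`` are decay knobs with alpha + beta < 1 so the
    iteration contracts; defaults 0.5 / 0.2.
    """
    params = dict(params or {})
    alpha = float(params.get("alpha", 0.5))
    beta = float(params.get("beta", 0.2))
    tol = float(params.get("tol", 1e-6))
    max_sweeps = int(params.get("max_sweeps", 100))
    if not partition.covers(g):
        raise ValidationError("partition does not cover the graph")
    blocks = partition.blocks
    nc = len(blocks)
    flags = []
    nodes = list(g.nodes)
    max_deg = max((g.degree(v) for v in nodes), default=0)
    base = {v: (g.degree(v) / max_deg if max_deg else 0.0) for v in nodes}
    I = [{v: (base[v] if v in blocks[i] else 0.0) for v in nodes}
         for i in range(nc)]
    pairs = list(combinations(range(nc), 2))
    if not pairs:
        flags.append("degenerate: single community, no holes to span")
        scores = {v: 0.0 for v in nodes}
        return SHScoreTable(method="his", scores=scores,
                            top=_topk(scores, k), flags=flags,
                            params={"alpha": alpha, "beta": beta})
    und = {v: _contacts(g, v) for v in nodes}
    H = {S: {v: 0.0 for v in nodes} for S in pairs}
    converged = False
    for _ in range(max_sweeps):
        delta = 0.0
        for S in pairs:
            i, j = S
            for v in nodes:
                h = min(I[i][v], I[j][v])
                delta = max(delta, abs(h - H[S][v]))
                H[S][v] = h
        for i in range(nc):
            rel = [S for S in pairs if i in S]
            for v in nodes:
                best = I[i][v]
                for u in und[v]:
                    for S in rel:
                        cand = alpha * I[i][u] + beta * H[S][u]
                        if cand > best:
                            best = cand
                delta = max(delta, best - I[i][v])
                I[i][v] = best
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("HIS did not converge; returning last iterate",
                      RuntimeWarning)
        flags.append("not converged")
    scores = {v: max(H[S][v] for S in pairs) for v in nodes}
    return SHScoreTable(method="his", scores=scores, top=_topk(scores, k),
                        flags=flags,
                        params={"alpha": alpha, "beta": beta})


# ---------------------------------------------------------------------------
# MaxD: greedy min-cut reduction


def _min_vertex_cut(g: Graph, side_a: set, side_b: set,
                    removed: set) -> int:
    """Max-flow = min vertex cut separating two node sets.

    Node-splitting construction: every node gets capacity 1; edges are
    uncapacitated.  BFS augmenting paths (unit capacities keep this
    cheap).
    """
    INF = float("inf")
    cap: dict = {}
    nodes = [v for v in g.nodes if v not in removed]

    def add(a, b, c):
        cap[(a, b)] = cap.get((a, b), 0) + c
        cap.setdefault((b, a), 0)

    for v in nodes:
        add(("in", v), ("out", v), 1)
    for u, v, _ in g.edges():
        if u in removed or v in removed:
            continue
        add(("out", u), ("in", v), INF)
        if not g.directed:
            add(("out", v), ("in", u), INF)
    S, T = ("S", None), ("T", None)
    for v in side_a:
        if v not in removed:
            add(S, ("in", v), INF)
    for v in side_b:
        if v not in removed:
            add(("out", v), T, INF)
    adj: dict = {}
    for (a, b) in cap:
        adj.setdefault(a, []).append(b)
    flow = 0
    while True:
        parent = {S: None}
        queue = [S]
        found = False
        for x in queue:
            for y in adj.get(x, []):
                if y not in parent and cap[(x, y)] > 0:
                    parent[y] = x
                    if y == T:
                        found = True
                        break
                    queue.append(y)
            if found:
                break
        if not found:
            return flow
        # bottleneck is always 1 (every path crosses an in->out arc)
        y = T
        while parent[y] is not None:
            x = parent[y]
            cap[(x, y)] -= 1
            cap[(y, x)] += 1
            y = x
        flow += 1
        if flow > g.n_nodes:  # safety: cut cannot exceed n
            return flow


def detect_maxd(g: Graph, partition: CommunityPartition,
                k: int = 1) -> SHScoreTable:
    """Greedy selection of nodes whose removal shrinks the community
    min-cuts the most.

    Each round recomputes, for every remaining candidate, the sum over
    community pairs of the minimum vertex cut still connecting them,
    and removes the candidate giving the largest decrease.  Ties are
    broken toward the candidate with fewer intra-community ties (a
    spanner sits between groups, not inside one), then by label.
    Selected nodes score their decrease; all others 0.
    """
    _check_k(g, k)
    if len(partition.blocks) < 2:
        raise ValidationError("MaxD needs at least two communities")
    if not partition.covers(g):
        raise ValidationError("partition does not cover the graph")
    pairs = list(combinations(range(len(partition.blocks)), 2))
    removed: set = set()

    def total_cut() -> int:
        return sum(_min_vertex_cut(g, partition.blocks[i] - removed,
                                   partition.blocks[j] - removed, removed)
                   for i, j in pairs)

    block = partition.block_of()
    intra = {v: sum(1 for u in _contacts(g, v) if block[u] == block[v])
             for v in g.nodes}
    scores = {v: 0.0 for v in g.nodes}
    selected = []
    current = total_cut()
    for _ in range(k):
        if current == 0:
            break
        best_v, best_key = None, None
        for v in g.nodes:
            if v in removed:
                continue
            removed.add(v)
            c = total_cut()
            removed.discard(v)
            key = (c, intra[v], str(v))
            if best_key is None or key < best_key:
                best_v, best_key = v, key
        best_cut = best_key[0]
        if best_v is None or best_cut >= current:
            break
        scores[best_v] = float(current - best_cut)
        selected.append(best_v)
        removed.add(best_v)
        current = best_cut
    top = selected + [v for v in _topk(scores, g.n_nodes)
                      if v not in selected][:max(0, k - len(selected))]
    return SHScoreTable(method="maxd", scores=scores, top=top[:k],
                        params={"k": k})


# ---------------------------------------------------------------------------
# removal-based centrality detectors (Greedy family, ICC family)


def _pair_distance_sum_without(g: Graph, v) -> float:
    """Pairwise hop-distance sum over V \\ {v} with v deleted; a
    disconnected pair contributes n instead of infinity."""
    nodes = [u for u in g.nodes if u != v]
    pen = float(g.n_nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    total = 0.0
    for s in nodes:
        dist = _bfs_removed(g, s, v)
        for t in nodes:
            if idx[t] <= idx[s]:
                continue
            total += dist.get(t, pen)
    return total


def _bfs_removed(g: Graph, s, removed) -> dict:
    dist = {s: 0}
    queue = [s]
    for u in queue:
        du = dist[u]
        for w in g.adj[u]:
            if w == removed or w in dist:
                continue
            dist[w] = du + 1
            queue.append(w)
    return dist


def _pair_distance_sum_with(g: Graph, exclude) -> float:
    """Pairwise distance sum over V \\ {exclude}, with v usable."""
    nodes = [u for u in g.nodes if u != exclude]
    pen = float(g.n_nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    total = 0.0
    for s in nodes:
        dist = _bfs_dist(g.adj, s)
        for t in nodes:
            if idx[t] <= idx[s]:
                continue
            total += dist.get(t, pen)
    return total


def greedy_removal_score(g: Graph, v) -> float:
    """score(v) = sum over pairs s,t != v of d_{G-v}(s,t) - d_G(s,t),
    with a penalty of n replacing an infinite (disconnected) distance."""
    return _pair_distance_sum_without(g, v) - _pair_distance_sum_with(g, v)


def detect_greedy(g: Graph, k: int = 1) -> SHScoreTable:
    """Exact removal scores for every node; top-k by distance inflation."""
    _check_k(g, k)
    scores = {v: greedy_removal_score(g, v) for v in g.nodes}
    return SHScoreTable(method="greedy", scores=scores,
                        top=_topk(scores, k), params={"k": k})


def detect_ap_greedy(g: Graph, k: int = 1) -> SHScoreTable:
    """Removal scores evaluated only at articulation points.

    Non-cut nodes get the lower bound 0; the top-k therefore equals the
    exact Greedy top-k whenever all of Greedy's top-k are articulation
    points (deleting a cut vertex always inflates distances more than
    deleting a non-cut vertex of the same neighborhood).
    """
    _check_k(g, k)
    aps = articulation_points(g)
    scores = {v: (greedy_removal_score(g, v) if v in aps else 0.0)
              for v in g.nodes}
    return SHScoreTable(method="ap_greedy", scores=scores,
                        top=_topk(scores, k),
                        params={"k": k, "articulation_points": len(aps)})


def _ball_bfs(g: Graph, s, allowed: Optional[set], removed) -> dict:
    dist = {s: 0}
    queue = [s]
    for u in queue:
        du = dist[u]
        for w in g.adj[u]:
            if w == removed or w in dist:
                continue
            if allowed is not None and w not in allowed:
                continue
            dist[w] = du + 1
            queue.append(w)
    return dist


def icc_score(g: Graph, v, ball: Optional[set] = None) -> float:
    """Shortest-path inflation caused by removing v — the quantity behind
    inverse-closeness-centrality ranking.

    score(v) = sum_{s<t, s,t != v} [d_{G-v}(s,t) - d_G(s,t)], where a
    disconnected pair contributes the penalty distance n instead of
    infinity.  Restricting to *ball* gives the localized evaluation used
    by the pruned variant; the penalty stays the global n so bounded and
    exact evaluations are on the same scale.
    """
    nodes = [u for u in g.nodes
             if u != v and (ball is None or u in ball)]
    idx = {u: i for i, u in enumerate(nodes)}
    pen = float(g.n_nodes)
    allowed = None if ball is None else set(ball)
    total = 0.0
    for s in nodes:
        before = _ball_bfs(g, s, allowed, removed=None)
        after = _ball_bfs(g, s, allowed, removed=v)
        for t in nodes:
            if idx[t] <= idx[s]:
                continue
            d0 = min(float(before.get(t, pen)), pen)
            d1 = min(float(after.get(t, pen)), pen)
            total += d1 - d0
    return total


def detect_icc(g: Graph, k: int = 1) -> SHScoreTable:
    """Exact harmonic-loss scores for every node."""
    _check_k(g, k)
    scores = {v: icc_score(g, v) for v in g.nodes}
    return SHScoreTable(method="icc", scores=scores, top=_topk(scores, k),
                        params={"k": k})


def detect_bicc(g: Graph, k: int = 1, bound: int = 2) -> SHScoreTable:
    """Radius-bounded prune of the harmonic-loss score.

    Every node is first scored inside its radius-*bound* ball (a cheap
    localized evaluation); the strongest candidates are then re-scored
    exactly.  With bound >= diameter the ball is the whole graph and the
    result equals the exact evaluation for every node.
    """
    _check_k(g, k)
    if bound < 1:
        raise ValidationError("bound must be >= 1")
    approx = {}
    for v in g.nodes:
        dist = _bfs_dist(g.adj, v)
        ball = {u for u, d in dist.items() if d <= bound}
        whole = len(dist) == g.n_nodes and max(dist.values(), default=0) <= bound
        approx[v] = icc_score(g, v, ball=None if whole else ball)
    survivors = _topk(approx, max(2 * k, k + 5))
    scores = dict(approx)
    for v in survivors:
        scores[v] = icc_score(g, v)
    return SHScoreTable(method="bicc", scores=scores, top=_topk(scores, k),
                        params={"k": k, "bound": bound,
                                "survivors": len(survivors)})


def detect_ap_bicc(g: Graph, k: int = 1) -> SHScoreTable:
    """Harmonic-loss evaluation restricted to articulation points."""
    _check_k(g, k)
    aps = articulation_points(g)
    scores = {v: (icc_score(g, v) if v in aps else 0.0) for v in g.nodes}
    return SHScoreTable(method="ap_bicc", scores=scores,
                        top=_topk(scores, k),
                        params={"k": k, "articulation_points": len(aps)})


# ---------------------------------------------------------------------------
# WeakTie


def detect_weak_tie(g: Graph, partition: CommunityPartition, k: int = 1,
                    variant: str = "local") -> SHScoreTable:
    """Cross-community tie counting.

    ``local``: each cross-block tie of v contributes 1/(1 + number of
    common neighbors with the tied alter) — the weaker (less embedded)
    the tie, the more it signals a hole being bridged.  ``bi``: counts
    cross-block ties; in directed graphs only reciprocated ones.
    """
    if variant not in ("local", "bi"):
        raise ValidationError(f"unknown WeakTie variant {variant!r}")
    if not partition.covers(g):
        raise ValidationError("partition does not cover the graph")
    block = partition.block_of()
    flags = []
    if len(partition.blocks) < 2:
        flags.append("degenerate: single community, all scores zero")
    nbr = {v: set(_contacts(g, v)) for v in g.nodes}
    scores = {}
    for v in g.nodes:
        s = 0.0
        for u in g.adj[v]:
            if u == v or block[u] == block[v]:
                continue
            if variant == "bi":
                if not g.directed or g.has_edge(u, v):
                    s += 1.0
            else:
                common = len(nbr[v] & nbr[u])
                s += 1.0 / (1.0 + common)
        scores[v] = s
    return SHScoreTable(method=f"weaktie_{variant}", scores=scores,
                        top=_topk(scores, k), flags=flags,
                        params={"k": k, "variant": variant})
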