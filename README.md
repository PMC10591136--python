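# holenet

Interdisciplinary network analysis with a structural-hole focus: a
self-contained Python toolkit for building graphs, moving them between
the common interchange formats, computing the standard centrality and
connectivity metrics, and — its specialty — finding **structural-hole
spanners**, the broker nodes that bridge otherwise disconnected
communities.

It is aimed at researchers who work with networks across disciplines
(protein interaction networks, collaboration and citation graphs,
social networks) and need, in one place:

- a **graph data model** over arbitrary hashable node labels, directed
  or undirected, weighted, with attribute maps and cached-view
  ("dirty flag") snapshots that rebuild only after mutations;
- **I/O for eight formats**: whitespace edge lists, GraphML, GML,
  Pajek, UCINET DL (full matrix and edge list), GEXF, GraphViz DOT and
  a portable native JSON;
- **metrics**: multi-source Dijkstra, Brandes betweenness, closeness,
  PageRank, k-core decomposition (linear-time bucket peeling), local
  clustering and triangle counting;
- **Burt's structural-hole metrics** — effective size, efficiency,
  constraint, hierarchy — and nine spanner detectors (HIS, MaxD,
  Greedy, AP_Greedy, ICC, BICC, AP_BICC, WeakTie-Local, WeakTie-Bi);
- **community detection** (Girvan–Newman, label propagation) with
  Newman–Girvan modularity;
- **node embeddings** (DeepWalk, node2vec, LINE) with a built-in
  skip-gram negative-sampling trainer, deterministic given a seed;
- a **parallel layer** that distributes per-node metrics over a worker
  pool with results identical to the serial computation.

## The core ideas

A *structural hole* is a gap between two groups that lack direct ties;
the node spanning it brokers information flow.  Burt's constraint
quantifies the opposite of brokerage,

$$C_v = \sum_{j \in N(v)} \Big(p_{vj} + \sum_{q} p_{vq}\, p_{qj}\Big)^2,$$

where $p_{ij} = (z_{ij}+z_{ji}) / \sum_k (z_{ik}+z_{ki})$ is the
proportional tie strength: low constraint means $v$'s contacts are
spread over unconnected clusters.  Effective size
$\mathrm{ES}(v) = \sum_j \big[1 - \sum_{q\neq j} p_{vq} m_{jq}\big]$
discounts a node's contacts by their redundancy, and hierarchy measures
how concentrated $C_v$ is in a single contact.  The spanner detectors
rank nodes by complementary signals: fixed points of a
community-importance recurrence (HIS), reduction of the minimum vertex
cut between communities (MaxD), the inflation of pairwise shortest
paths when the node is removed (Greedy/ICC families, with
articulation-point and radius-bounded accelerations), and weak
cross-community ties (WeakTie).

## A worked example

```python
import holenet as hn

g = hn.two_cliques_bridge(5)          # two 5-cliques + broker node 10
part = hn.CommunityPartition(blocks=[set(range(5)) | {10},
                                     set(range(5, 10))])

print(hn.detect_his(g, part).top)     # [10]
print(hn.detect_greedy(g).top)        # [10]
print(round(hn.constraint(g, 10), 3)) # 0.5  (low: rich in holes)
print(round(hn.constraint(g, 1), 3))  # 0.733 (high: embedded in a clique)
```

The broker is ranked first by every detector; its constraint 0.5 is far
below the 0.733 of a clique-interior node, which is exactly Burt's
reading: the broker's two contacts are not connected to each other, so
it faces little constraint and spans the hole between the cliques.

The `examples/` directory contains one short script per capability
(statistics and cached views, format conversion, Burt metrics on the
karate-club network, spanner detection, communities, embeddings,
parallel equality); each prints the numbers it computes and a line on
what they mean.  A thin command-line front end mirrors the library:

```bash
holenet generate --er 10000,20000 --seed 7 --out g.graphml
holenet stats g.graphml             # n=10000, m=20000, avg degree 4.0
holenet sh-detect g.graphml --method greedy --k 5
```

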