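# Methods

This note documents the models, conventions and design choices behind
holenet, in the order a user meets them.

## Graph model and cached views

Graphs are simple (no parallel edges): re-adding an existing edge
overwrites its weight and attributes.  Self-loops may be stored but are
excluded from the clustering coefficient, k-core and Burt metrics,
which is the conventional reading of those quantities.  Edge weights
must be strictly positive; unweighted inputs get weight 1.0.  Neighbor
iteration is insertion-ordered, so every algorithm in the package is
deterministic without sorting tricks.

`Graph.snapshot()` returns a `CachedView` — a frozen node order, an
in/out/total degree table and a compact CSR adjacency.  The graph keeps
a version counter bumped on every mutation (the dirty-flag pattern); a
view built against an older version reports `valid == False` and any
query through it first rebuilds, so view answers always equal a
from-scratch construction.  Performance contracts: O(1) amortized edge
insert/remove, O(deg) neighbor scans, O(n+m) view rebuilds.

Whole-graph statistics follow the benchmark conventions: average degree
is 2m/n for **both** directed and undirected graphs (the mean of total
in+out degree), density is 2m/(n(n−1)) undirected and m/(n(n−1))
directed.

## File formats

Eight dialects are supported: edge list, GraphML, GML, Pajek, UCINET DL
(FULLMATRIX and EDGELIST1), GEXF (1.2draft static), GraphViz DOT, and a
native JSON form `{"directed", "nodes": [{"id", "attrs"}], "edges":
[{"u", "v", "weight", "attrs"}]}` that replaces byte-level pickling
with something portable.  Conventions:

- Node labels are serialized as text.  Readers return text labels by
  default; `label_type="auto"` coerces integer-looking labels back to
  integers (round-trip fidelity beats convenience, so the coercion is
  opt-in).
- Writers emit a canonical ordering — nodes and edges sorted by label
  text, undirected edges oriented smaller-label-first — so
  write∘read∘write is byte-stable.
- Edge lists use whitespace separation, `#` comments and an optional
  third column parsed as weight; a leading `# directed=true` comment
  records orientation, since the bare format cannot.
- UCINET DL FULLMATRIX writing requires node labels 0..n−1 (a pure
  matrix has no place for arbitrary labels — a `CapabilityError` says
  so); EDGELIST1 carries a LABELS section and a `DIRECTED=YES/NO`
  keyword.  A symmetric full matrix reads as undirected.
- GraphML/GEXF attributes are typed string/int/float/bool; anything
  else is serialized as text.  GML has no boolean type, so booleans
  survive GML as text.
- The DOT reader handles plain node/edge statements with attribute
  lists; `subgraph`/cluster syntax is rejected with a clear error.
- `detect_format` goes by file extension first, then content sniffing
  (XML root element, `DL` header, `*Vertices`, `graph {`/`digraph {`,
  `graph [`, leading `{`), falling back to edge list.

## Generators

`erdos_renyi_gnm(n, m)` samples exactly m distinct edges uniformly
without replacement and without self-loops (G(n, m) rather than
G(n, p), because benchmark tables print exact edge counts; G(n, p) is
also provided).  Node labels are 0..n−1.  All randomness flows through
one integer seed.

The fixture zoo covers star, path, cycle, complete graphs, the bundled
34-node/78-edge Zachary karate club (native JSON inside the package)
and `two_cliques_bridge(k)`: two k-cliques whose only connection is a
broker node adjacent to one member of each clique.  That broker is a
perfect structural-hole spanner by construction, which makes the
fixture the canonical ground truth for the detector suite.

## Metrics

- **Multi-source Dijkstra** uses an indexed binary heap with O(log n)
  decrease-key.  Unreachable distances are `inf`, never a sentinel
  number.
- **Betweenness** is Brandes' dependency accumulation; unnormalized by
  default (flag for (n−1)(n−2)/2 resp. (n−1)(n−2) normalization), each
  unordered pair counted once on undirected graphs.  Passing `sources`
  restricts accumulation to those sources — the sampling mode used on
  very large networks — and with all nodes as sources it equals the
  full computation exactly.
- **Closeness** uses the component-wise convention (r−1)/Σd with r the
  number of reachable nodes; this keeps disconnected graphs meaningful
  instead of zeroing them.  Isolated nodes score 0.
- **PageRank** is power iteration on the out-degree transition with
  uniform teleport; dangling mass is redistributed uniformly;
  convergence is an L1 change below `tol` (default 1e-8), with a
  warning and the best iterate on non-convergence.
- **k-core** is Matula–Beck peeling over an O(n+m) bucket ordering of
  degrees.  Directed graphs are peeled on total (in+out) degree, so a
  neighbor may lose two arcs when one node is removed — the peel
  decrements per arc, not per neighbor.
- **Clustering/triangles** work on the undirected neighbor sets;
  triangle counting rejects directed input (orientation conventions
  are out of scope).

## Burt metrics

Proportional tie strength symmetrizes weights:
p_ij = (z_ij+z_ji)/Σ_k(z_ik+z_ki); it sums to one over the contacts of
any non-isolated node.  Effective size discounts each contact j by its
redundancy Σ_q p_vq·m_jq with m_jq = z_jq / max_k z_jk (j's tie to q
scaled by j's strongest tie).  Constraint is
C_v = Σ_j (p_vj + Σ_q p_vq p_qj)²; hierarchy is the Coleman–Theil
concentration of the c_vj terms, Σ_j (c_vj/(C/N)) ln(c_vj/(C/N)) /
(N ln N), defined as 0 for nodes with fewer than two contacts (the
N ln N denominator degenerates).  Isolated nodes raise an
undefined-statistic error for effective size/efficiency/constraint.

Closed forms used as anchors: a star center with three leaves has
effective size 3, constraint 1/3, hierarchy 0; any triangle node has
effective size 1 and constraint 1.125; a pendant leaf has effective
size 1 and constraint 1.

## Spanner detectors

All detectors return per-node scores plus a deterministic top-k (score
descending, then label ascending as text), and all are invariant under
node relabeling.

- **HIS** maintains a community-importance score I(v, C_i) per
  community and a bridging score H(v, S) per community pair, iterating
  H(v,S) = min_{i∈S} I(v,C_i) and I(v,C_i) = max(I(v,C_i),
  max over neighbors u and pairs S∋i of α·I(u,C_i) + β·H(u,S)) to a
  fixed point (tolerance 1e-6, 100 sweeps).  α=0.5, β=0.2 by default;
  α+β<1 makes the iteration contract.  Importance initializes to
  degree/max-degree inside a node's own community.  The reported score
  is the maximal bridging score over community pairs.  A single-block
  partition is flagged degenerate (no holes to span).
- **MaxD** greedily removes the node that most decreases the sum over
  community pairs of the minimum vertex cut still connecting them
  (max-flow with unit node capacities via node splitting and BFS
  augmenting paths).  Cut-decrease ties are broken toward the
  candidate with fewer intra-community ties — the spanner-like choice,
  since a broker sits between groups rather than inside one — then by
  label.
- **Greedy** scores v by the total inflation of pairwise shortest-path
  distances when v is removed, with a newly disconnected pair
  contributing the penalty n in place of infinity; this keeps scores
  finite and strongly favors cut vertices.  **AP_Greedy** evaluates
  that score only at articulation points (linear-time low-link
  traversal) and gives all other nodes the lower bound 0; its top-k
  equals Greedy's whenever Greedy's top-k are all articulation points.
- **ICC** uses the same removal-inflation quantity (the basis of
  inverse-closeness-centrality ranking) evaluated exactly for every
  node.  An earlier harmonic-sum variant was rejected because it ties
  the broker with its two contact nodes on the bridge fixture; the
  distance-inflation form ranks the broker strictly first, which is
  the behavior the detector exists to deliver.  **BICC** first scores
  every node inside its radius-`bound` ball (a cheap localized
  evaluation with the same global penalty scale), re-scores the
  strongest candidates exactly, and returns the top-k; with bound ≥
  diameter it equals ICC exactly.  **AP_BICC** evaluates only
  articulation points.
- **WeakTie** counts cross-community ties: the `local` variant weights
  each cross tie by 1/(1 + common neighbors with the alter) — the less
  embedded the tie, the more it signals a hole — and the `bi` variant
  counts only reciprocated cross ties on directed graphs.  On the
  bridge fixture the broker's WeakTie score ties with the opposite
  clique's contact node (both have exactly one bare cross tie by
  construction), so the broker is maximal rather than unique there.

HIS and MaxD need a community partition; the CLI falls back to seeded
label propagation when none is supplied and records that in the result
parameters.

## Communities

Modularity is Q = Σ_c [L_c/m − (D_c/2m)²] with weighted intra-block
edge mass and degree mass.  Girvan–Newman recomputes full edge
betweenness after every removal and breaks ties by lexicographically
smallest endpoint pair; it yields the component partition after each
removal and `best_girvan_newman` keeps the modularity maximizer (first
on ties).  Label propagation updates asynchronously in a seeded
shuffled order with seeded tie-breaks, so a fixed seed gives a fixed
partition.  Only these two detectors are in scope.

## Embeddings

DeepWalk and node2vec generate walk corpora (uniform, resp.
second-order biased with return parameter p and in-out parameter q
through alias tables; p=q=1 reproduces the uniform law exactly) and
train skip-gram with negative sampling: unigram^0.75 noise
distribution, plain SGD with a linear learning-rate decay from 0.025
to 1% of that, single worker, hence bit-deterministic per seed.  LINE
samples edges proportionally to weight (alias method) and optimizes
first-order (shared endpoint vectors) or second-order (separate
context vectors) proximity; `order="both"` concatenates two
independently trained d/2 halves.

Defaults are the conventional d=128, 10 walks × length 80, window 5,
5 negatives; the test suite and examples use smaller settings (d=16,
6–8 walks × length 20) which already separate the two cliques of the
bridge fixture cleanly.  Vectors initialize uniform in (−0.5/d, 0.5/d);
nodes that never occur in a training pair (isolated nodes) keep a zero
vector.  SDNE-style deep autoencoders and t-SNE plotting are out of
scope; the embedding matrix exports to TSV for external tooling.

## Parallel layer

`parallel_node_metric` distributes closeness, betweenness, hierarchy
and local clustering over a process pool: the node list (source list
for betweenness) is split into contiguous chunks of ceil(n/workers)
over the cached node order, each worker computes against a read-only
copy of the graph, and partials are merged in fixed chunk order.
Integer/rational results are bitwise identical to serial; betweenness
sums floating partial dependency tables, identical to well below 1e-12
at the sizes tested.  Parallelism is not always a win — cheap per-node
metrics like the clustering coefficient can be dominated by
inter-process communication — so the worker count is an explicit knob.

## What the synthetic data does and does not show

The generators emulate the *sizes and degree structure* of published
benchmark networks (G(n, m) at 10k–330k nodes reproduces any printed
average degree and density exactly, since both are functions of n and
m only) and the *topological ground truth* for spanner detection (the
bridge fixture).  They do not emulate heavy-tailed degree
distributions, clustering, or community size imbalance of real
networks, so passing tests demonstrate algorithmic correctness and
benchmark-statistic fidelity, not predictive performance on any
particular real dataset.  Wall-clock speedups of the parallel layer
are hardware-dependent and deliberately not asserted anywhere; the
tested contract is result equality.

## Problem sizes used in the checks

The acceptance run generates the eight Erdős–Rényi benchmark
configurations at full size (10k–200k nodes) and twelve real-network
size twins (up to 325,729 nodes / 1,497,134 edges); oracle-equivalence
checks run on 100 seeded random graphs per algorithm at the sizes
where exhaustive oracles are feasible (n ≤ 12 for path enumeration,
n ≤ 50 for peeling, n ≤ 30 for Floyd–Warshall); round-trips use 50
random weighted graphs across all eight dialects; serial/parallel
equality uses 25 graphs × worker counts {1,2,4,8}; embeddings use the
12-node bridge fixture over 5 seeds per method.  Two published density
figures (for the email-EuAll and web-NotreDame rows) are inconsistent
with m/(n(n−1)) at the printed n and m and are treated as typos: the
corresponding average degrees are reproduced, the two densities are
not asserted.
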