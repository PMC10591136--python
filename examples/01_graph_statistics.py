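"""Build a benchmark-style random network and read off its statistics.

G(n, m) fixes the edge count exactly, so the average degree 2m/n and
the density come out exactly at their designed values — the same
figures a benchmark table would print for an Erdős–Rényi network of
that size.
"""

import holenet as hn

g = hn.erdos_renyi_gnm(10_000, 20_000, seed=1)
print(f"nodes          : {g.n_nodes}")
print(f"edges          : {g.n_edges}")
print(f"average degree : {hn.average_degree(g):.4f}")   # 2m/n = 4.0
print(f"density        : {hn.density(g):.4g}")          # ~4e-4

# the cached view snapshots node order and degrees; it goes stale (and
# transparently rebuilds) as soon as the graph mutates
view = g.snapshot()
print(f"view valid     : {view.valid}")
g.add_edge(0, 9_999)
print(f"after mutation : valid={view.valid}, "
      f"degree(0) via view = {view.degree(0)} (rebuilt)")
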