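"""Burt's structural-hole metrics on the karate-club network.

Low constraint marks nodes whose contacts are spread across otherwise
unconnected parts of the network — the classic signature of a broker.
The two club leaders (nodes 0 and 33) have the largest effective sizes
and the lowest constraint.
"""

import holenet as hn

g = hn.karate_club()
rows = []
for v in g.nodes:
    rows.append((v, hn.effective_size(g, v), hn.efficiency(g, v),
                 hn.constraint(g, v), hn.hierarchy(g, v)))

rows.sort(key=lambda r: r[3])  # most hole-rich (lowest constraint) first
print(f"{'node':>4} {'eff.size':>9} {'efficiency':>10} "
      f"{'constraint':>10} {'hierarchy':>9}")
for v, es, eff, c, h in rows[:8]:
    print(f"{v:>4} {es:9.3f} {eff:10.3f} {c:10.3f} {h:9.3f}")
print("...")
print("lowest-constraint nodes bridge the most structural holes")
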