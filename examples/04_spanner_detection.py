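"""Detect the structural-hole spanner bridging two cliques.

Two 5-cliques are joined through a single broker node (label 10); all
detection strategies — score recurrences, min-cut reduction, removal-
based centralities and weak-tie counting — should single it out.
"""

import holenet as hn

k = 5
g = hn.two_cliques_bridge(k)
broker = 2 * k
partition = hn.CommunityPartition(
    blocks=[set(range(k)) | {broker}, set(range(k, 2 * k))])

print(f"graph: two {k}-cliques + broker node {broker}\n")
detectors = {
    "HIS": hn.detect_his(g, partition),
    "MaxD": hn.detect_maxd(g, partition),
    "Greedy": hn.detect_greedy(g),
    "AP_Greedy": hn.detect_ap_greedy(g),
    "ICC": hn.detect_icc(g),
    "BICC": hn.detect_bicc(g, bound=2),
    "AP_BICC": hn.detect_ap_bicc(g),
    "WeakTie-Local": hn.detect_weak_tie(g, partition, variant="local"),
    "WeakTie-Bi": hn.detect_weak_tie(g, partition, variant="bi"),
}
for name, table in detectors.items():
    top = table.top[0]
    print(f"{name:14s} top-1 = node {top:2d} "
          f"(score {table.scores[top]:.4f})"
          f"{'  <- broker' if top == broker else ''}")
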