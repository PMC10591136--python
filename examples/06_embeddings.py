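"""Embed a two-community graph and measure how well the methods
separate the communities.

The separation statistic is mean intra-clique cosine similarity minus
mean inter-clique cosine similarity; a clearly positive value means
nodes from the same clique sit together in the embedding space.
"""

import holenet as hn
from holenet.embedding import clique_separation

g = hn.two_cliques_bridge(6)
groups = [set(range(6)), set(range(6, 12))]

for name, emb in [
    ("DeepWalk", hn.deepwalk(g, d=16, walks_per_node=8, walk_length=20,
                             window=4, epochs=2, seed=0)),
    ("node2vec", hn.node2vec(g, d=16, p=0.5, q=2.0, walks_per_node=8,
                             walk_length=20, window=4, epochs=2, seed=0)),
    ("LINE", hn.line(g, d=16, order="1", samples=20_000, seed=0)),
]:
    sep = clique_separation(emb, groups)
    print(f"{name:9s} separation = {sep:+.3f} "
          f"({'communities separated' if sep > 0 else 'no separation'})")
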