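import networkx as nx
import pytest

import holenet as hn


def to_networkx(g: hn.Graph):
    """Convert a holenet graph to networkx for oracle comparisons."""
    G = nx.DiGraph() if g.directed else nx.Graph()
    G.add_nodes_from(g.nodes)
    for u, v, data in g.edges():
        G.add_edge(u, v, weight=data["weight"])
    return G


@pytest.fixture
def path3():
    return hn.fixture("path", n=3)


@pytest.fixture
def star3():
    return hn.fixture("star", leaves=3)


@pytest.fixture
def triangle():
    return hn.fixture("complete", n=3)


@pytest.fixture
def broker4():
    """Two 4-cliques joined through broker node 8."""
    return hn.two_cliques_bridge(4)


@pytest.fixture
def broker_partition4():
    return hn.CommunityPartition(blocks=[set(range(4)) | {8},
                                         set(range(4, 8))])


@pytest.fixture
def karate():
    return hn.karate_club()
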