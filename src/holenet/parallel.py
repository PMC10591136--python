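"""Worker-pool execution of node-decomposable metrics.

Closeness, betweenness, hierarchy and the local clustering coefficient
can all be computed per node (or, for betweenness, per source) with no
interdependencies, so the node set is split into contiguous chunks over
the cached node order, each worker computes its chunk against a
read-only copy of the graph, and the partial tables are merged back in
node order.  The merged result equals the serial computation — exactly
for integer/rational paths, within 1e-12 for floating accumulations —
regardless of the worker count or chunk completion order.

Note that parallelism is not always a win: cheap per-node metrics such
as the clustering coefficient can be dominated by inter-process
communication overhead, so the worker count is a knob, not a default.
"""

from __future__ import annotations

import math
import multiprocessing as mp
from typing import Optional, Sequence, Union

from .exceptions import ValidationError
from .graph import Graph
from .metrics import (CentralityTable, brandes_partial,
                      closeness_centrality, local_clustering)
from .structural_holes import SHScoreTable, hierarchy

__all__ = ["parallel_node_metric", "PARALLEL_METRICS"]

PARALLEL_METRICS = ("closeness", "betweenness", "hierarchy", "clustering")


def _chunks(items: list, workers: int) -> list:
    size = math.ceil(len(items) / workers) if items else 1
    return [items[i:i + size] for i in range(0, len(items), size)]


def _work(args):
    g, metric, chunk, weighted = args
    if metric == "closeness":
        return closeness_centrality(g, sources=chunk).scores
    if metric == "betweenness":
        return brandes_partial(g, chunk, weighted=weighted)
    if metric == "hierarchy":
        return {v: hierarchy(g, v) for v in chunk}
    if metric == "clustering":
        return {v: local_clustering(g, v) for v in chunk}
    raise ValidationError(f"unknown metric {metric!r}")


def parallel_node_metric(g: Graph, metric: str, workers: int = 1,
                         sources: Optional[Sequence] = None,
                         normalized: bool = False,
                         weighted: bool = False,
                         ) -> Union[CentralityTable, SHScoreTable]:
    """Compute a per-node metric with *workers* processes.

    ``metric`` is one of ``closeness``, ``betweenness``, ``hierarchy``,
    ``clustering``.  For betweenness the split is over source nodes and
    the partial dependency tables are summed; for the others the split
    is over the nodes being scored.  ``sources`` restricts the
    computation (sampled mode for closeness/betweenness, node subset for
    the local metrics).
    """
    if workers < 1:
        raise ValidationError("workers must be >= 1")
    if metric not in PARALLEL_METRICS:
        raise ValidationError(f"metric must be one of {PARALLEL_METRICS}")
    view = g.snapshot()
    items = list(view.node_order) if sources is None else list(sources)
    chunks = _chunks(items, workers)
    tasks = [(g, metric, chunk, weighted) for chunk in chunks if chunk]
    if workers == 1 or len(tasks) <= 1:
        partials = [_work(t) for t in tasks]
    else:
        ctx = mp.get_context()
        with ctx.Pool(processes=min(workers, len(tasks))) as pool:
            partials = pool.map(_work, tasks)
    if metric == "betweenness":
        merged = {v: 0.0 for v in view.node_order}
        for part in partials:  # chunk order is fixed -> deterministic merge
            for v in view.node_order:
                merged[v] += part[v]
        if not g.directed:
            merged = {v: x / 2.0 for v, x in merged.items()}
        if normalized:
            n = g.n_nodes
            denom = ((n - 1) * (n - 2) / 2.0 if not g.directed
                     else float((n - 1) * (n - 2)))
            if denom > 0:
                merged = {v: x / denom for v, x in merged.items()}
        return CentralityTable(
            metric="betweenness", scores=merged, normalized=normalized,
            sampled_sources=None if sources is None else tuple(items))
    merged = {}
    for part in partials:
        merged.update(part)
    merged = {v: merged[v] for v in items}  # canonical node_order merge
    if metric == "hierarchy":
        return SHScoreTable(method="hierarchy", scores=merged,
                            params={"workers": workers})
    return CentralityTable(metric=metric, scores=merged,
                           sampled_sources=None if sources is None
                           else tuple(items))
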