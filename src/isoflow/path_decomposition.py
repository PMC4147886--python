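"""Decompose an optimal flow into (s, t)-path flows, i.e. isoforms.

By the flow decomposition theorem any DAG flow is a superposition of at
most |E| (s, t)-path flows.  Decomposition is not unique in general; the
strategy here repeatedly extracts the path carrying the maximum amount of
flow (the maximum-bottleneck path, found by dynamic programming in
topological order), subtracts its bottleneck from its arcs, and repeats
until the remaining flow is a negligible fraction of the original.  The
result is therefore one sparse solution among possibly several with the
same objective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bin_graph import SINK, SOURCE, BinGraph, node_key, path_to_isoform
from .gene_model import Isoform
from .objective import Flow


@dataclass
class IsoformSet:
    """Decoded isoforms with abundances, plus the paths they came from and
    the undistributed residual flow."""

    isoforms: tuple[Isoform, ...]
    paths: tuple[tuple, ...] = ()
    residual: float = 0.0

    def __len__(self) -> int:
        return len(self.isoforms)

    def __iter__(self):
        return iter(self.isoforms)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([iso.abundance for iso in self.isoforms])

    @property
    def exon_chains(self) -> set[tuple[int, ...]]:
        return {iso.exons for iso in self.isoforms}


def max_flow_path(flow: Flow, graph: BinGraph) -> tuple[tuple, float]:
    """(s, t)-path maximizing the minimum arc flow along it.

    Dynamic programming in topological order; ties are broken in favor of
    fewer vertices, then the lexicographically smallest vertex sequence.
    Raises on a flow with no positive path to the sink.
    """
    order = graph.topological_order()
    G = graph.graph
    # best[v] = (bottleneck, path-from-s as tuple); paths compared by
    # (length, key sequence) for deterministic tie-breaking
    best: dict = {SOURCE: (np.inf, (SOURCE,))}

    def path_rank(p: tuple) -> tuple:
        return (len(p), tuple(node_key(v) for v in p))

    for v in order:
        if v not in best:
            continue
        b_v, p_v = best[v]
        for w in G.successors(v):
            f = flow.value(v, w)
            if f <= 0:
                continue
            cand = (min(b_v, f), p_v + (w,))
            cur = best.get(w)
            if (
                cur is None
                or cand[0] > cur[0]
                or (cand[0] == cur[0] and path_rank(cand[1]) < path_rank(cur[1]))
            ):
                best[w] = cand
    if SINK not in best:
        raise ValueError("flow carries no positive (s,t)-path")
    bottleneck, path = best[SINK]
    return path, float(bottleneck)


def decompose_flow(
    flow: Flow, graph: BinGraph, min_frac: float = 1e-8
) -> IsoformSet:
    """Greedy max-bottleneck flow decomposition.

    Stops once the remaining total flow drops below `min_frac` times the
    original total flow.  The superposition of the returned path flows
    reproduces the input flow up to the stopping residual, and at most
    |E| paths are extracted.
    """
    work = flow.copy()
    total0 = work.total
    isoforms: list[Isoform] = []
    paths: list[tuple] = []
    if total0 <= 0:
        return IsoformSet((), (), residual=max(0.0, total0))
    max_paths = graph.n_arcs
    remaining = total0
    while remaining > min_frac * total0 and len(paths) < max_paths:
        try:
            path, w = max_flow_path(work, graph)
        except ValueError:
            # solver round-off can strand a sub-tolerance amount of flow
            # that no longer reaches the sink; treat it as residual
            break
        if w <= 0:
            break
        for u, v in zip(path, path[1:]):
            work.arc_flow[(u, v)] = max(0.0, work.value(u, v) - w)
        isoforms.append(path_to_isoform(path, graph, abundance=w))
        paths.append(path)
        remaining = work.total
    return IsoformSet(tuple(isoforms), tuple(paths), residual=remaining)
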