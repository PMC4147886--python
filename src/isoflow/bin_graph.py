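"""DAG of read bins whose (s, t)-paths biject with candidate isoforms.

Vertices are the bins with positive effective length that are consistent
with a set of candidate splice junctions; an arc connects two bins that
can be produced by reads starting at successive positions of the same
isoform.  A source s is connected to every bin that can hold the leftmost
read of an isoform, and every bin that can hold the rightmost read is
connected to a sink t.  The graph generalizes the splicing graph: when
all exons are at least as long as the read, bins are single exons and
exon-exon junctions.

Only bins whose total internal exon length is at most L - 2 can have a
positive effective length, so for a fixed read length L the vertex count
is polynomial in the number of exons even though the number of candidate
isoforms is exponential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .gene_model import Bin, GeneModel, Isoform, effective_length

logger = logging.getLogger(__name__)

#: Distinguished source and sink vertices.
SOURCE: str = "s"
SINK: str = "t"


def node_key(node: Hashable) -> tuple:
    """Deterministic total order on graph vertices: s < bins (lexicographic
    by exon tuple) < t."""
    if node == SOURCE:
        return (0,)
    if node == SINK:
        return (2,)
    return (1,) + tuple(node)


@dataclass
class BinGraph:
    """Bin DAG of one gene, with the gene model and read length attached."""

    gene: GeneModel
    read_length: int
    graph: nx.DiGraph
    pruned_bins: tuple[Bin, ...] = ()

    @property
    def bins(self) -> list[Bin]:
        """Graph vertices (excluding s, t), in deterministic order."""
        return [
            self.graph.nodes[v]["bin"]
            for v in sorted(self.graph.nodes, key=node_key)
            if v not in (SOURCE, SINK)
        ]

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def arcs(self) -> list[tuple]:
        return sorted(self.graph.edges, key=lambda e: (node_key(e[0]), node_key(e[1])))

    def topological_order(self) -> list:
        return list(nx.lexicographical_topological_sort(self.graph, key=node_key))


def _validate_junctions(junctions: Iterable[tuple[int, int]], n: int) -> set[tuple[int, int]]:
    out = set()
    for i, j in junctions:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"junction ({i}, {j}) out of range for {n} exons")
        if j <= i:
            raise ValueError(
                f"junction ({i}, {j}) is not a forward pair; cyclic or "
                "inverted junction input is not supported"
            )
        out.add((int(i), int(j)))
    return out


def _enumerate_bins(
    gene: GeneModel, junctions: set[tuple[int, int]], L: int
) -> dict[tuple[int, ...], Bin]:
    """All junction-consistent bins with positive effective length.

    Depth-first extension of exon chains; a chain is abandoned once its
    internal length exceeds L - 2, because the effective-length formula is
    then non-positive for it and every extension of it.
    """
    lengths = gene.exon_lengths
    succ: dict[int, list[int]] = {i: [] for i in range(gene.n_exons)}
    for i, j in junctions:
        succ[i].append(j)
    for i in succ:
        succ[i].sort()

    found: dict[tuple[int, ...], Bin] = {}
    stack: list[tuple[tuple[int, ...], int]] = [((e,), 0) for e in range(gene.n_exons)]
    while stack:
        chain, l_int = stack.pop()
        eff = effective_length([lengths[i] for i in chain], L)
        if eff > 0:
            found[chain] = Bin(chain, eff)
        last = chain[-1]
        for nxt in succ[last]:
            # internal exons of the extended chain are chain[1:], so the
            # current last exon becomes internal (except when len(chain)==1)
            new_int = l_int + (lengths[last] if len(chain) >= 2 else 0)
            if new_int <= L - 2:
                stack.append((chain + (nxt,), new_int))
    return found


def starting_bins(
    gene: GeneModel, bins: Iterable[Bin], L: int
) -> set[Bin]:
    """Bins that can contain a read at the leftmost position of an isoform:
    a read of length L placed at base 1 of the bin's first exon overlaps
    exactly the bin's exons."""
    lengths = gene.exon_lengths
    out = set()
    for b in bins:
        lens = [lengths[i] for i in b.exons]
        if len(lens) == 1:
            if L <= lens[0]:
                out.add(b)
        else:
            head = sum(lens[:-1])
            if head < L <= sum(lens):
                out.add(b)
    return out


def stopping_bins(
    gene: GeneModel, bins: Iterable[Bin], L: int
) -> set[Bin]:
    """Mirror of :func:`starting_bins`: a read ending at the last base of
    the bin's last exon overlaps exactly the bin's exons."""
    lengths = gene.exon_lengths
    out = set()
    for b in bins:
        lens = [lengths[i] for i in b.exons]
        if len(lens) == 1:
            if L <= lens[0]:
                out.add(b)
        else:
            tail = sum(lens[1:])
            if tail < L <= sum(lens):
                out.add(b)
    return out


def build_graph(
    gene: GeneModel, junctions: Iterable[tuple[int, int]], read_length: int
) -> BinGraph:
    """Construct the bin DAG for one gene.

    Arcs implement a one-position slide of a read along an isoform:
    dropping the bin's first exon, appending one junction-linked exon at
    the end, or both simultaneously when geometry forces it (the read
    leaves the first exon exactly when its end enters the next one).
    Vertices that cannot lie on any (s, t)-path are pruned.
    """
    L = int(read_length)
    if L < 1:
        raise ValueError(f"read length must be >= 1, got {read_length}")
    jset = _validate_junctions(junctions, gene.n_exons)
    lengths = gene.exon_lengths
    succ: dict[int, list[int]] = {i: [] for i in range(gene.n_exons)}
    for i, j in sorted(jset):
        succ[i].append(j)

    vertices = _enumerate_bins(gene, jset, L)
    G = nx.DiGraph()
    G.add_node(SOURCE)
    G.add_node(SINK)
    for chain, b in vertices.items():
        G.add_node(chain, bin=b)

    for chain in vertices:
        lens = [lengths[i] for i in chain]
        tail = sum(lens[1:])  # length of exons after the first
        # drop-first: read slides off exon chain[0] into bin chain[1:]
        if len(chain) >= 2:
            inner = sum(lens[1:-1])
            if L >= inner + 2 and L <= tail and chain[1:] in vertices:
                G.add_edge(chain, chain[1:])
        for nxt in succ[chain[-1]]:
            # drop-first and append-next in one slide: the read starts at
            # the last base of the first exon and ends at the last base of
            # the last exon, which forces L == tail + 1
            if L == tail + 1:
                w = chain[1:] + (nxt,)
                if w in vertices:
                    G.add_edge(chain, w)
            # append-next only: the read end crosses into the next exon
            # while the start stays inside the first exon
            a = L - tail  # bases of the first exon covered at the crossing
            if 2 <= a <= lens[0]:
                w = chain + (nxt,)
                if w in vertices:
                    G.add_edge(chain, w)

    bins = set(vertices.values())
    for b in starting_bins(gene, bins, L):
        G.add_edge(SOURCE, b.exons)
    for b in stopping_bins(gene, bins, L):
        G.add_edge(b.exons, SINK)

    # prune vertices not on any (s, t)-path
    reachable = nx.descendants(G, SOURCE) | {SOURCE}
    coreach = nx.ancestors(G, SINK) | {SINK}
    keep = reachable & coreach
    pruned = [
        G.nodes[v]["bin"] for v in G.nodes if v not in keep and v not in (SOURCE, SINK)
    ]
    if pruned:
        logger.info(
            "gene %s: pruned %d bins not on any (s,t)-path: %s",
            gene.gene_id,
            len(pruned),
            [b.exons for b in pruned],
        )
    G.remove_nodes_from([v for v in list(G.nodes) if v not in keep])
    if SOURCE not in G:
        G.add_node(SOURCE)
    if SINK not in G:
        G.add_node(SINK)

    if not nx.is_directed_acyclic_graph(G):  # pragma: no cover - defensive
        raise RuntimeError("bin graph is not acyclic")
    return BinGraph(gene=gene, read_length=L, graph=G, pruned_bins=tuple(sorted(pruned)))


def path_to_isoform(path: Sequence, graph: BinGraph, abundance: float = 0.0) -> Isoform:
    """Decode an (s, t)-path into the isoform whose reads trace the path:
    the increasing union of exon indices over the path's bins."""
    if len(path) < 3 or path[0] != SOURCE or path[-1] != SINK:
        raise ValueError(f"not an (s,t)-path: {path!r}")
    G = graph.graph
    for u, v in zip(path, path[1:]):
        if not G.has_edge(u, v):
            raise ValueError(f"arc ({u!r}, {v!r}) not in graph")
    exons: set[int] = set()
    for v in path[1:-1]:
        exons.update(v)
    return Isoform(tuple(sorted(exons)), abundance=abundance)


def enumerate_paths(
    graph: BinGraph, max_paths: int = 100_000
) -> tuple[list[tuple], bool]:
    """All (s, t)-paths in lexicographic order, truncated at `max_paths`.

    Returns (paths, overflowed).  Intended for small genes: the number of
    paths grows exponentially with the number of exons.
    """
    G = graph.graph
    paths: list[tuple] = []
    overflow = False
    stack: list[tuple[tuple, ...]] = [(SOURCE,)]
    while stack:
        prefix = stack.pop()
        node = prefix[-1]
        if node == SINK:
            if len(paths) >= max_paths:
                overflow = True
                break
            paths.append(prefix)
            continue
        for nxt in sorted(G.successors(node), key=node_key, reverse=True):
            stack.append(prefix + (nxt,))
    return paths, overflow
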