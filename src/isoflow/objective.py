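"""Poisson likelihood of bin counts and its path- and flow-space forms.

Counts y_v of reads in bin v are modeled as independent Poisson variables
with intensity delta_v = l_v * sum_j U_jv theta_j, where l_v is the bin's
effective length, theta_j the abundance of isoform j in reads per base,
and U the bin/isoform incidence.  The penalized estimator minimizes

    sum_v [delta_v - y_v log delta_v]  +  lambda * sum_j theta_j

over theta >= 0 (the log y! constants do not depend on theta and are
dropped during optimization, but included in reported log-likelihoods).
Because every isoform is an (s, t)-path of the bin graph and delta_v
depends only on the total abundance of isoforms passing through v, the
same objective can be written on a flow f over the graph's arcs:

    sum_v [l_v f_v - y_v log(l_v f_v)]  +  lambda * (flow into t)

with f_v the inflow at vertex v.  All functions here use the
minimization convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .bin_graph import SINK, SOURCE, BinGraph, node_key
from .gene_model import Bin

#: Relative conservation tolerance accepted by flow_objective.
CONSERVATION_TOL = 1e-6


@dataclass
class BinCounts:
    """Read counts for the bins of one gene."""

    bins: tuple[Bin, ...]
    counts: np.ndarray
    read_length: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.bins),):
            raise ValueError(
                f"{len(self.bins)} bins but counts of shape {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")
        self._by_exons = {b.exons: i for i, b in enumerate(self.bins)}

    @property
    def q(self) -> int:
        return len(self.bins)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def count_for(self, exons: tuple[int, ...]) -> float:
        i = self._by_exons.get(tuple(exons))
        return 0.0 if i is None else float(self.counts[i])


def align_counts(graph: BinGraph, counts: BinCounts) -> tuple[np.ndarray, np.ndarray, dict]:
    """Vectors (y, l) over graph.bins order plus diagnostics about counts
    on bins absent from the graph (e.g. pruned vertices)."""
    bins = graph.bins
    vertex_keys = {b.exons for b in bins}
    y = np.array([counts.count_for(b.exons) for b in bins], dtype=float)
    l = np.array([b.effective_length for b in bins], dtype=float)
    orphans = {
        b.exons: float(c)
        for b, c in zip(counts.bins, counts.counts)
        if c > 0 and b.exons not in vertex_keys
    }
    diagnostics = {
        "orphan_bins": orphans,
        "orphan_reads": float(sum(orphans.values())),
        "retained_reads": float(y.sum()),
    }
    return y, l, diagnostics


def poisson_loglik(
    counts: Sequence[float], intensities: Sequence[float], include_constants: bool = True
) -> float:
    """Poisson log-likelihood sum_v [-delta_v + y_v log delta_v - log(y_v!)].

    Uses the 0*log 0 = 0 convention; a positive count with zero intensity
    yields -inf.  Negative intensities are an error.
    """
    y = np.asarray(counts, dtype=float)
    d = np.asarray(intensities, dtype=float)
    if y.shape != d.shape:
        raise ValueError(f"shape mismatch: counts {y.shape}, intensities {d.shape}")
    if np.any(d < 0):
        raise ValueError("negative Poisson intensity")
    if np.any((y > 0) & (d == 0)):
        return -np.inf
    pos = y > 0
    value = -float(d.sum())
    value += float((y[pos] * np.log(d[pos])).sum())
    if include_constants:
        value -= float(gammaln(y + 1).sum())
    return value


@dataclass
class PathDesign:
    """Explicit bin/isoform incidence for a small set of candidate paths.

    Row j of `incidence` marks the bins of candidate j (U_jv = 1 when bin v
    belongs to isoform j).  Only used by brute-force oracles and refits:
    the number of candidates m grows exponentially with exon count.
    """

    incidence: np.ndarray  # (m, q) 0/1
    theta: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.incidence.ndim != 2:
            raise ValueError("incidence must be 2-d (m x q)")
        if self.theta.shape != (self.incidence.shape[0],):
            raise ValueError(
                f"{self.incidence.shape[0]} candidates but theta of shape {self.theta.shape}"
            )

    @property
    def m(self) -> int:
        return self.incidence.shape[0]


def path_objective(design: PathDesign, counts: BinCounts, lam: float) -> float:
    """Penalized negative log-likelihood in path space (constants dropped):
    sum_v [delta_v - y_v log delta_v] + lambda * sum_j theta_j with
    delta_v = l_v * sum_j U_jv theta_j."""
    if design.incidence.shape[1] != counts.q:
        raise ValueError(
            f"design has {design.incidence.shape[1]} bins, counts have {counts.q}"
        )
    if np.any(design.theta < 0):
        raise ValueError("negative abundance")
    l = np.array([b.effective_length for b in counts.bins], dtype=float)
    y = counts.counts
    delta = l * (design.theta @ design.incidence)
    if np.any((y > 0) & (delta <= 0)):
        return np.inf
    pos = y > 0
    value = float(delta.sum()) - float((y[pos] * np.log(delta[pos])).sum())
    return value + float(lam) * float(design.theta.sum())


@dataclass
class Flow:
    """Nonnegative arc values on a bin graph satisfying conservation at
    every vertex except the source and sink."""

    graph: BinGraph
    arc_flow: dict[tuple, float]

    def __post_init__(self) -> None:
        G = self.graph.graph
        for (u, v), f in self.arc_flow.items():
            if not G.has_edge(u, v):
                raise ValueError(f"arc ({u!r}, {v!r}) not in graph")
            if f < 0:
                raise ValueError(f"negative flow {f} on arc ({u!r}, {v!r})")

    def value(self, u, v) -> float:
        return self.arc_flow.get((u, v), 0.0)

    def vertex_inflow(self, v) -> float:
        return sum(self.arc_flow.get((u, v), 0.0) for u in self.graph.graph.predecessors(v))

    def vertex_outflow(self, v) -> float:
        return sum(self.arc_flow.get((v, w), 0.0) for w in self.graph.graph.successors(v))

    @property
    def total(self) -> float:
        """Total flow from source to sink."""
        return self.vertex_outflow(SOURCE)

    def conservation_gap(self) -> float:
        """Largest |inflow - outflow| over internal vertices."""
        gap = 0.0
        for v in self.graph.graph.nodes:
            if v in (SOURCE, SINK):
                continue
            gap = max(gap, abs(self.vertex_inflow(v) - self.vertex_outflow(v)))
        return gap

    def copy(self) -> "Flow":
        return Flow(self.graph, dict(self.arc_flow))


def superpose_paths(
    graph: BinGraph, path_weights: Iterable[tuple[Sequence, float]]
) -> Flow:
    """Superimpose (s, t)-path flows: each path contributes its weight to
    every arc along it."""
    arc_flow: dict[tuple, float] = {}
    for path, w in path_weights:
        if w < 0:
            raise ValueError(f"negative path weight {w}")
        for u, v in zip(path, path[1:]):
            arc_flow[(u, v)] = arc_flow.get((u, v), 0.0) + float(w)
    return Flow(graph, arc_flow)


def flow_objective(
    flow: Flow, counts: BinCounts, lam: float, cons_tol: float = CONSERVATION_TOL
) -> float:
    """Penalized negative log-likelihood of a flow (constants dropped):
    sum_v [l_v f_v - y_v log(l_v f_v)] + lambda * (flow into sink)."""
    gap = flow.conservation_gap()
    scale = max(1.0, flow.total)
    if gap > cons_tol * scale:
        raise ValueError(
            f"flow violates conservation: gap {gap:.3g} for total flow {flow.total:.3g}"
        )
    value = 0.0
    for b in flow.graph.bins:
        y = counts.count_for(b.exons)
        delta = b.effective_length * flow.vertex_inflow(b.exons)
        if delta <= 0:
            if y > 0:
                return np.inf
            continue
        value += delta - y * np.log(delta)
    return value + float(lam) * flow.vertex_inflow(SINK)
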