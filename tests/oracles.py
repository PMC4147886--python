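"""Independent brute-force oracles used to check the package's fast paths.

Everything here deliberately avoids the code paths it is used to verify:
effective lengths are counted by sliding a window base by base; candidate
isoforms are enumerated recursively over exon subsets; and the penalized
likelihood is minimized in the explicit (exponential) path space with a
generic bound-constrained quasi-Newton method.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from isoflow import BinCounts, BinGraph, enumerate_paths


def brute_effective_length(lengths: list[int], L: int) -> int:
    """Count read starts assigning a read to the bin, by direct sliding."""
    M = sum(lengths)
    count = 0
    for p in range(0, max(0, M - L + 1)):
        starts_in_first = p < lengths[0]
        ends_in_last = p + L > M - lengths[-1] and p + L <= M
        if starts_in_first and ends_in_last:
            count += 1
    return count


def enumerate_exon_chains(
    n_exons: int,
    junctions: set[tuple[int, int]],
    lengths: list[int],
    L: int,
) -> set[tuple[int, ...]]:
    """All candidate isoforms: junction-consistent increasing exon chains
    of total length >= L (recursive enumeration, independent of the bin
    graph)."""
    chains: set[tuple[int, ...]] = set()

    def extend(chain: list[int]) -> None:
        if sum(lengths[i] for i in chain) >= L:
            chains.add(tuple(chain))
        for j in range(chain[-1] + 1, n_exons):
            if (chain[-1], j) in junctions:
                extend(chain + [j])

    for e in range(n_exons):
        extend([e])
    return chains


def path_space_design(graph: BinGraph, counts: BinCounts):
    """Explicit incidence of graph bins in every enumerated (s,t)-path."""
    paths, overflow = enumerate_paths(graph, max_paths=10_000)
    assert not overflow
    idx = {b.exons: i for i, b in enumerate(counts.bins)}
    U = np.zeros((len(paths), counts.q))
    for j, p in enumerate(paths):
        for v in p[1:-1]:
            U[j, idx[v]] = 1.0
    return paths, U


def path_space_solve(
    graph: BinGraph, counts: BinCounts, lam: float
) -> tuple[float, np.ndarray]:
    """Minimize the penalized objective over explicit path abundances."""
    _, U = path_space_design(graph, counts)
    l = np.array([b.effective_length for b in counts.bins], dtype=float)
    y = counts.counts
    m = U.shape[0]
    pos = y > 0
    d0 = 1e-8 * np.maximum(1.0, y)

    def fun_grad(theta):
        delta = l * (theta @ U)
        cost = delta.copy()
        dcost = np.ones_like(delta)
        d = delta[pos]
        dd0 = d0[pos]
        yy = y[pos]
        safe = d >= dd0
        logt = np.where(
            safe,
            np.log(np.maximum(d, dd0)),
            np.log(dd0) + (d - dd0) / dd0 - (d - dd0) ** 2 / (2 * dd0**2),
        )
        dlog = np.where(safe, 1 / np.maximum(d, dd0), 1 / dd0 - (d - dd0) / dd0**2)
        cost[pos] -= yy * logt
        dcost[pos] -= yy * dlog
        return cost.sum() + lam * theta.sum(), U @ (l * dcost) + lam

    theta0 = np.full(m, max(1e-3, y.sum() / max(1.0, l.sum())))
    res = optimize.minimize(
        fun_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * m,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return float(res.fun), np.maximum(res.x, 0.0)


def single_path_fits(graph: BinCounts, counts: BinCounts, lam: float) -> list[float]:
    """Optimal penalized objective of every single-path model (closed form
    theta* = sum_p y / (sum_p l + lam)); +inf when a counted bin is off
    the path."""
    paths, U = path_space_design(graph, counts)
    l = np.array([b.effective_length for b in counts.bins], dtype=float)
    y = counts.counts
    out = []
    for j in range(U.shape[0]):
        on = U[j] > 0
        if np.any((y > 0) & ~on):
            out.append(np.inf)
            continue
        ysum, lsum = y[on].sum(), l[on].sum()
        theta = ysum / (lsum + lam) if ysum > 0 else 0.0
        if theta <= 0:
            out.append(0.0 if ysum == 0 else np.inf)
            continue
        delta = l[on] * theta
        val = delta.sum() - float((y[on][y[on] > 0] * np.log(delta[y[on] > 0])).sum())
        out.append(val + lam * theta)
    return out
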