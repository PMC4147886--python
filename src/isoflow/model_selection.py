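"""Regularization path fitting and BIC model selection.

For large lambda the l1 penalty forces few isoforms; decreasing lambda
admits more.  Each candidate support found along a decreasing lambda grid
is re-fitted by unpenalized maximum likelihood (removing the l1
shrinkage) and scored with a Schwarz-type criterion

    BIC = loglik - (k / 2) * log(q)

where k is the number of isoforms with non-negligible abundance and q the
number of bins carrying reads; the fit with the largest BIC wins, ties
going to the sparser model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .bin_graph import BinGraph
from .flow_solver import SolverError, solve_min_cost_flow
from .gene_model import Isoform, isoform_bins
from .objective import BinCounts, Flow, align_counts, poisson_loglik
from .path_decomposition import IsoformSet, decompose_flow

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tuning knobs of the regularization path.

    lambda_grid: strictly decreasing positive penalty weights; by default
        20 log-spaced values from the total read count down to 1e-4 of it
        (Poisson gradients scale with counts, so the top of that range
        suppresses every isoform and the bottom is effectively unpenalized).
    tol: relative optimality tolerance passed to the flow solver.
    min_frac: stopping fraction of the flow decomposition.
    abundance_floor_frac: isoforms below this fraction of the total
        abundance are treated as numerical zeros.
    """

    lambda_grid: Optional[Sequence[float]] = None
    tol: float = 1e-6
    min_frac: float = 1e-8
    bic_refit: bool = True
    seed: int = 0
    abundance_floor_frac: float = 1e-6
    n_lambda: int = 20

    def grid_for(self, counts: BinCounts) -> np.ndarray:
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValueError("lambda grid must be strictly decreasing and positive")
            return grid
        hi = max(counts.total, 1.0)
        return np.geomspace(hi, hi * 1e-4, self.n_lambda)


@dataclass
class FitResult:
    """One point of the regularization path."""

    lam: float
    isoform_set: IsoformSet
    loglik: float
    n_isoforms: int
    bic: float = np.nan


def refit_ml(
    support: Sequence[Isoform], graph: BinGraph, counts: BinCounts
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood abundances restricted to a fixed isoform set.

    Maximizes the Poisson log-likelihood over theta >= 0 for the given
    support (a convex problem of small dimension) and reports the value
    including the log(y!) constants.  An empty support scores the all-zero
    intensity model.
    """
    y, l, _ = align_counts(graph, counts)
    if len(support) == 0:
        theta = np.zeros(0)
        return theta, poisson_loglik(y, np.zeros_like(y))
    bins = graph.bins
    idx = {b.exons: i for i, b in enumerate(bins)}
    m = len(support)
    U = np.zeros((m, len(bins)))
    for j, iso in enumerate(support):
        for b in isoform_bins(iso, graph.gene, graph.read_length):
            if b.exons in idx:
                U[j, idx[b.exons]] = 1.0
    pos = y > 0
    delta0 = 1e-8 * np.maximum(1.0, y)

    def fun_grad(theta):
        delta = l * (theta @ U)
        cost = delta.copy()
        dcost = np.ones_like(delta)
        d = delta[pos]
        d0 = delta0[pos]
        yy = y[pos]
        safe = d >= d0
        logterm = np.where(
            safe,
            np.log(np.maximum(d, d0)),
            np.log(d0) + (d - d0) / d0 - (d - d0) ** 2 / (2 * d0**2),
        )
        dlog = np.where(safe, 1.0 / np.maximum(d, d0), 1.0 / d0 - (d - d0) / d0**2)
        cost[pos] -= yy * logterm
        dcost[pos] -= yy * dlog
        return cost.sum(), U @ (l * dcost)

    theta0 = np.array([max(iso.abundance, 1e-6) for iso in support])
    res = optimize.minimize(
        fun_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * m,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    theta = np.maximum(res.x, 0.0)
    delta = l * (theta @ U)
    return theta, poisson_loglik(y, delta)


def _floor_filter(iso_set: IsoformSet, floor_frac: float) -> list[Isoform]:
    total = float(iso_set.abundances.sum()) if len(iso_set) else 0.0
    if total <= 0:
        return []
    floor = floor_frac * total
    return [iso for iso in iso_set if iso.abundance > floor]


def _score_support(
    support: Sequence[Isoform],
    graph: BinGraph,
    counts: BinCounts,
    lam: float,
    log_n: float,
    config: FitConfig,
    paths: tuple = (),
    residual: float = 0.0,
) -> FitResult:
    if config.bic_refit:
        theta, loglik = refit_ml(support, graph, counts)
    else:
        # score the l1-shrunk abundances directly
        theta = np.array([iso.abundance for iso in support])
        y, l, _ = align_counts(graph, counts)
        idx = {b.exons: i for i, b in enumerate(graph.bins)}
        delta = np.zeros_like(y)
        for iso, t in zip(support, theta):
            for b in isoform_bins(iso, graph.gene, graph.read_length):
                if b.exons in idx:
                    delta[idx[b.exons]] += b.effective_length * t
        loglik = poisson_loglik(y, delta)
    refit = tuple(
        Isoform(iso.exons, abundance=float(t))
        for iso, t in zip(support, theta)
        if t > 0
    )
    iso_set = IsoformSet(refit, paths, residual)
    k = len(refit)
    bic = loglik - 0.5 * k * log_n
    return FitResult(float(lam), iso_set, float(loglik), k, float(bic))


def fit_path(
    graph: BinGraph, counts: BinCounts, config: Optional[FitConfig] = None
) -> list[FitResult]:
    """Fit the flow problem along the lambda grid and score candidate
    supports.

    Each solve is warm-started from the previous lambda.  Because the
    Poisson log-likelihood is a barrier at zero intensity, every bin with
    reads keeps a little flow at any penalty, so the decomposition of one
    optimal flow can carry low-abundance tails; each decomposition is
    therefore expanded into its nested prefixes in extraction order
    (largest paths first), every distinct support across the whole grid
    is refitted by maximum likelihood once, and all are scored with BIC
    using the number of mapped reads as the Schwarz sample size.
    """
    config = config or FitConfig()
    grid = config.grid_for(counts)
    log_n = np.log(max(2.0, counts.total))
    fits: list[FitResult] = []
    seen: set[frozenset] = set()
    warm: Optional[Flow] = None
    for lam in grid:
        try:
            flow = solve_min_cost_flow(graph, counts, lam, tol=config.tol, warm_start=warm)
        except SolverError as err:
            logger.warning("lambda=%.4g: %s; skipping grid point", lam, err)
            continue
        warm = flow
        decomposed = decompose_flow(flow, graph, min_frac=config.min_frac)
        support = _floor_filter(decomposed, config.abundance_floor_frac)
        for upto in range(1, len(support) + 1):
            key = frozenset(iso.exons for iso in support[:upto])
            if key in seen:
                continue
            seen.add(key)
            fit = _score_support(
                support[:upto], graph, counts, lam, log_n, config,
                paths=decomposed.paths[:upto], residual=decomposed.residual,
            )
            fits.append(fit)
            logger.debug(
                "lambda=%.4g: k=%d, loglik=%.4f, bic=%.4f",
                lam, fit.n_isoforms, fit.loglik, fit.bic,
            )
        if not support and frozenset() not in seen:
            seen.add(frozenset())
            fits.append(_score_support([], graph, counts, lam, log_n, config))
    return fits


def bic_select(fits: Sequence[FitResult]) -> FitResult:
    """The fit with the largest BIC; ties broken toward fewer isoforms,
    then toward the stronger penalty."""
    if not fits:
        raise ValueError("no fits to select from")
    return max(fits, key=lambda f: (f.bic, -f.n_isoforms, f.lam))


def quantify_gene(
    graph: BinGraph, counts: BinCounts, config: Optional[FitConfig] = None
) -> tuple[FitResult, list[FitResult]]:
    """Full pipeline for one gene: regularization path + BIC selection."""
    fits = fit_path(graph, counts, config)
    if not fits:
        raise SolverError("no successful fit on the lambda grid")
    return bic_select(fits), fits
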