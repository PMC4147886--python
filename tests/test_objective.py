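"""Likelihood evaluation and the path/flow objective equivalence."""

import math
import random

import numpy as np
import pytest

from isoflow import (
    Bin,
    BinCounts,
    PathDesign,
    enumerate_paths,
    flow_objective,
    path_objective,
    poisson_loglik,
    superpose_paths,
)
from conftest import random_counts, random_instance


class TestPoissonLoglik:
    def test_empty_model_zero(self):
        assert poisson_loglik([0, 0], [0.0, 0.0]) == 0.0

    def test_single_bin_value(self):
        # -3 + 3 log 3 - log 3! evaluated directly
        expected = -3 + 3 * math.log(3) - math.log(6)
        assert poisson_loglik([3], [3.0]) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-1.495923, abs=1e-6)

    def test_impossible_data(self):
        assert poisson_loglik([2], [0.0]) == -np.inf

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik([1], [-1.0])

    def test_constants_toggle(self):
        with_c = poisson_loglik([4], [2.0])
        without_c = poisson_loglik([4], [2.0], include_constants=False)
        assert without_c - with_c == pytest.approx(math.log(24), abs=1e-10)


class TestPathObjective:
    def test_zero_model_zero_data(self):
        design = PathDesign(np.ones((1, 1)), np.zeros(1))
        counts = BinCounts((Bin((0,), 5),), np.zeros(1), 10)
        assert path_objective(design, counts, 0.5) == 0.0

    def test_single_bin_worked_value(self):
        # l=2, y=4, theta=1, lam=0.5: (2 - 4 log 2) + 0.5
        design = PathDesign(np.ones((1, 1)), np.ones(1))
        counts = BinCounts((Bin((0,), 2),), np.array([4.0]), 10)
        expected = (2 - 4 * math.log(2)) + 0.5
        assert path_objective(design, counts, 0.5) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-0.27259, abs=1e-5)

    def test_lambda_zero_is_negative_loglik_without_constants(self):
        design = PathDesign(np.ones((2, 3)), np.array([0.7, 1.3]))
        bins = (Bin((0,), 4), Bin((0, 1), 3), Bin((1,), 6))
        counts = BinCounts(bins, np.array([5.0, 2.0, 9.0]), 10)
        delta = np.array([4, 3, 6]) * 2.0
        assert path_objective(design, counts, 0.0) == pytest.approx(
            -poisson_loglik(counts.counts, delta, include_constants=False), abs=1e-9
        )

    def test_dimension_mismatch(self):
        design = PathDesign(np.ones((1, 2)), np.ones(1))
        counts = BinCounts((Bin((0,), 2),), np.array([4.0]), 10)
        with pytest.raises(ValueError):
            path_objective(design, counts, 1.0)

    def test_midpoint_convexity(self):
        rng = np.random.default_rng(3)
        bins = tuple(Bin((i,), int(l)) for i, l in enumerate(rng.integers(1, 50, 4)))
        counts = BinCounts(bins, rng.poisson(10, 4).astype(float), 10)
        U = (rng.random((3, 4)) < 0.6).astype(float)
        U[:, 0] = 1.0  # ensure every bin reachable by some path
        U[0] = 1.0
        for _ in range(50):
            t1, t2 = rng.random(3) * 5, rng.random(3) * 5
            mid = 0.5 * (t1 + t2)
            f = lambda t: path_objective(PathDesign(U, t), counts, 1.0)
            assert f(mid) <= 0.5 * f(t1) + 0.5 * f(t2) + 1e-9


class TestFlowObjective:
    def test_zero_flow_zero_counts(self, fig_graph):
        flow = superpose_paths(fig_graph, [])
        bins = tuple(fig_graph.bins)
        counts = BinCounts(bins, np.zeros(len(bins)), 100)
        assert flow_objective(flow, counts, 1.0) == 0.0

    def test_zero_flow_positive_counts_infinite(self, fig_graph):
        flow = superpose_paths(fig_graph, [])
        bins = tuple(fig_graph.bins)
        y = np.zeros(len(bins))
        y[0] = 3
        counts = BinCounts(bins, y, 100)
        assert flow_objective(flow, counts, 1.0) == np.inf

    def test_conservation_violation_rejected(self, fig_graph):
        from isoflow import Flow, SOURCE

        arc = next(iter(fig_graph.graph.out_edges(SOURCE)))
        flow = Flow(fig_graph, {arc: 2.0})
        bins = tuple(fig_graph.bins)
        counts = BinCounts(bins, np.zeros(len(bins)), 100)
        with pytest.raises(ValueError):
            flow_objective(flow, counts, 1.0)

    def test_matches_path_objective_under_superposition(self):
        """Superimposing per-path flows reproduces the path-space
        objective value exactly (the flow reformulation)."""
        rng = random.Random(17)
        nprng = np.random.default_rng(17)
        done = 0
        while done < 100:
            gene, junctions, g = random_instance(rng)
            paths, overflow = enumerate_paths(g, max_paths=100)
            if overflow or not paths:
                continue
            counts = random_counts(g, nprng)
            idx = {b.exons: i for i, b in enumerate(counts.bins)}
            U = np.zeros((len(paths), counts.q))
            for j, p in enumerate(paths):
                for v in p[1:-1]:
                    U[j, idx[v]] = 1.0
            theta = nprng.random(len(paths)) * 3
            lam = float(nprng.choice([0.1, 1.0, 10.0]))
            obj_path = path_objective(PathDesign(U, theta), counts, lam)
            flow = superpose_paths(g, list(zip(paths, theta)))
            obj_flow = flow_objective(flow, counts, lam)
            assert obj_flow == pytest.approx(obj_path, rel=1e-10)
            done += 1
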