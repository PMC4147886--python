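"""Flow solver: transform accounting, closed forms, oracle equivalence."""

import math
import random

import numpy as np
import pytest

from isoflow import (
    Bin,
    BinCounts,
    GeneModel,
    SINK,
    build_graph,
    flow_objective,
    node_split_transform,
    solve_min_cost_flow,
)
from conftest import random_counts, random_instance
from oracles import path_space_solve, single_path_fits


def single_bin_instance(eff_len: int, y: float, L: int = 50):
    gene = GeneModel.from_lengths([eff_len + L - 1])
    g = build_graph(gene, set(), L)
    (b,) = g.bins
    assert b.effective_length == eff_len
    counts = BinCounts((b,), np.array([float(y)]), L)
    return g, b, counts


class TestNodeSplitTransform:
    def test_counts(self, fig_graph):
        bins = fig_graph.bins
        counts = BinCounts(tuple(bins), np.ones(len(bins)), 100)
        tg = node_split_transform(fig_graph, counts, 2.0)
        n_v = len(bins)
        assert len(tg.nodes) == 2 * n_v + 2
        assert len(tg.arcs) == n_v + fig_graph.n_arcs
        vertex_arcs = [a for a in tg.arcs if a.kind == "vertex"]
        assert len(vertex_arcs) == n_v
        sink_arcs = [a for a in tg.arcs if a.kind == "edge" and a.v == SINK]
        assert all(a.lam == 2.0 for a in sink_arcs) and sink_arcs

    def test_vertex_cost_value(self):
        from isoflow.flow_solver import TransformedArc

        arc = TransformedArc("u", "v", "vertex", eff_length=2.0, count=4.0)
        assert arc.cost(2.0) == pytest.approx(4 - 4 * math.log(4), abs=1e-10)
        assert 4 - 4 * math.log(4) == pytest.approx(-1.54518, abs=1e-5)

    def test_zero_count_cost_is_linear(self, fig_graph):
        bins = fig_graph.bins
        counts = BinCounts(tuple(bins), np.zeros(len(bins)), 100)
        tg = node_split_transform(fig_graph, counts, 0.0)
        arc = next(a for a in tg.arcs if a.kind == "vertex")
        assert arc.cost(3.0) == pytest.approx(3.0 * arc.eff_length)
        assert arc.cost(6.0) == pytest.approx(2 * arc.cost(3.0))


class TestClosedForms:
    @pytest.mark.parametrize("eff_len", [50, 200, 1000])
    @pytest.mark.parametrize("y", [3, 37, 5000])
    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0, 100.0])
    def test_single_path_abundance(self, eff_len, y, lam):
        """One bin on one path: stationarity of l*t - y log(l*t) + lam*t
        gives theta* = y / (l + lam)."""
        g, b, counts = single_bin_instance(eff_len, y)
        flow = solve_min_cost_flow(g, counts, lam)
        theta = flow.vertex_inflow(b.exons)
        assert theta == pytest.approx(y / (eff_len + lam), rel=1e-6)

    def test_saturated_model_at_lambda_zero(self):
        """With no penalty and disjoint paths, each bin's intensity hits
        its count (per-bin Poisson MLE)."""
        gene = GeneModel.from_lengths([150, 180])
        g = build_graph(gene, set(), 100)  # two isolated single-exon paths
        bins = tuple(g.bins)
        y = np.array([40.0, 70.0])
        counts = BinCounts(bins, y, 100)
        flow = solve_min_cost_flow(g, counts, 0.0)
        for b, yv in zip(bins, y):
            delta = b.effective_length * flow.vertex_inflow(b.exons)
            assert delta == pytest.approx(yv, rel=1e-5)

    def test_zero_counts_zero_flow(self, fig_graph):
        bins = tuple(fig_graph.bins)
        counts = BinCounts(bins, np.zeros(len(bins)), 100)
        flow = solve_min_cost_flow(fig_graph, counts, 1.0)
        assert flow.total == 0.0


class TestOracleEquivalence:
    def test_objective_matches_path_enumeration(self):
        """The flow optimum equals the explicit-path-space optimum of the
        same convex objective."""
        rng = random.Random(41)
        nprng = np.random.default_rng(41)
        done = 0
        while done < 15:
            gene, junctions, g = random_instance(rng)
            if not g.bins:
                continue
            from isoflow import enumerate_paths

            paths, overflow = enumerate_paths(g, max_paths=200)
            if overflow or not paths:
                continue
            counts = random_counts(g, nprng)
            for lam in (0.1, 1.0, 10.0):
                flow = solve_min_cost_flow(g, counts, lam)
                obj_flow = flow_objective(flow, counts, lam)
                obj_oracle, _ = path_space_solve(g, counts, lam)
                assert obj_flow <= obj_oracle + 1e-4 * max(1.0, abs(obj_oracle))
                assert obj_flow == pytest.approx(
                    obj_oracle, rel=1e-4, abs=1e-6
                )
            done += 1

    def test_beats_every_single_path_fit(self):
        rng = random.Random(43)
        nprng = np.random.default_rng(43)
        done = 0
        while done < 10:
            gene, junctions, g = random_instance(rng)
            from isoflow import enumerate_paths

            paths, overflow = enumerate_paths(g, max_paths=100)
            if overflow or not paths:
                continue
            counts = random_counts(g, nprng)
            flow = solve_min_cost_flow(g, counts, 1.0)
            obj = flow_objective(flow, counts, 1.0)
            for single in single_path_fits(g, counts, 1.0):
                assert obj <= single + 1e-6 * max(1.0, abs(single))
            done += 1


class TestFlowProperties:
    def test_total_flow_shrinks_with_lambda(self):
        rng = random.Random(47)
        nprng = np.random.default_rng(47)
        done = 0
        while done < 10:
            _, _, g = random_instance(rng)
            if not g.bins:
                continue
            counts = random_counts(g, nprng)
            if counts.total == 0:
                continue
            totals = []
            warm = None
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0):
                flow = solve_min_cost_flow(g, counts, lam, warm_start=warm)
                warm = flow
                totals.append(flow.total)
            assert all(
                a >= b - 1e-6 * max(1.0, a) for a, b in zip(totals, totals[1:])
            )
            done += 1

    def test_conservation(self):
        rng = random.Random(53)
        nprng = np.random.default_rng(53)
        done = 0
        while done < 15:
            _, _, g = random_instance(rng)
            counts = random_counts(g, nprng)
            flow = solve_min_cost_flow(g, counts, 1.0)
            assert flow.conservation_gap() <= 1e-8 * max(1.0, flow.total)
            done += 1
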