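"""Regularization path, maximum-likelihood refit and BIC selection."""

import math

import numpy as np
import pytest

from isoflow import (
    BinCounts,
    FitConfig,
    FitResult,
    GeneModel,
    Isoform,
    IsoformSet,
    bic_select,
    build_graph,
    fit_path,
    quantify_gene,
    refit_ml,
    simulate_counts,
)
from conftest import study_instance
from oracles import path_space_solve


def single_bin_graph(eff_len=2, L=50):
    gene = GeneModel.from_lengths([eff_len + L - 1])
    return gene, build_graph(gene, set(), L)


class TestRefit:
    def test_single_bin_closed_form(self):
        """One isoform over one bin: theta-hat = y / l and the reported
        log-likelihood includes the log y! constant."""
        gene, g = single_bin_graph(eff_len=2)
        counts = BinCounts(tuple(g.bins), np.array([4.0]), 50)
        theta, loglik = refit_ml([Isoform((0,))], g, counts)
        assert theta[0] == pytest.approx(2.0, rel=1e-6)
        expected = -4 + 4 * math.log(4) - math.log(24)
        assert loglik == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-1.63288, abs=1e-5)

    def test_exact_recovery_on_noiseless_counts(self):
        """Counts equal to their expectations refit to the true
        abundances."""
        gene, isoforms, graph = study_instance()
        from isoflow.simulator import expected_bin_intensities

        delta = expected_bin_intensities(gene, isoforms, graph.read_length)
        bins = tuple(graph.bins)
        y = np.array([delta.get(b.exons, 0.0) for b in bins])
        counts = BinCounts(bins, y, graph.read_length)
        theta, _ = refit_ml([Isoform(i.exons) for i in isoforms], graph, counts)
        for t_hat, iso in zip(theta, isoforms):
            assert t_hat == pytest.approx(iso.abundance, rel=1e-5)

    def test_nested_support_never_decreases_loglik(self):
        gene, isoforms, graph = study_instance()
        counts = simulate_counts(gene, isoforms, graph.read_length, seed=2)
        support = [Isoform(i.exons) for i in isoforms]
        _, ll2 = refit_ml(support, graph, counts)
        _, ll3 = refit_ml(support + [Isoform((0, 5))], graph, counts)
        assert ll3 >= ll2 - 1e-6

    def test_empty_support(self):
        gene, g = single_bin_graph()
        counts = BinCounts(tuple(g.bins), np.array([0.0]), 50)
        theta, loglik = refit_ml([], g, counts)
        assert len(theta) == 0 and loglik == 0.0
        counts2 = BinCounts(tuple(g.bins), np.array([3.0]), 50)
        _, loglik2 = refit_ml([], g, counts2)
        assert loglik2 == -np.inf


class TestBicSelect:
    def _fit(self, lam, k, loglik, bic):
        iso_set = IsoformSet(tuple(Isoform((i,), 1.0) for i in range(k)))
        return FitResult(lam, iso_set, loglik, k, bic)

    def test_equal_likelihood_prefers_sparser(self):
        fits = [self._fit(1.0, 1, -10.0, -10.5), self._fit(0.5, 2, -10.0, -11.0)]
        assert bic_select(fits).n_isoforms == 1

    def test_single_fit(self):
        fit = self._fit(1.0, 2, -5.0, -6.0)
        assert bic_select([fit]) is fit

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bic_select([])


class TestFitPath:
    def test_all_zero_counts_selects_empty_model(self, fig_graph):
        bins = tuple(fig_graph.bins)
        counts = BinCounts(bins, np.zeros(len(bins)), 100)
        fits = fit_path(fig_graph, counts, FitConfig(n_lambda=5))
        assert all(f.n_isoforms == 0 for f in fits)

    def test_single_isoform_recovered_noiselessly(self):
        """High-coverage counts from one isoform select exactly that
        isoform."""
        gene = GeneModel.from_lengths([300, 200, 250])
        iso = Isoform((0, 1, 2), abundance=5.0)
        g = build_graph(gene, {(0, 1), (1, 2)}, 100)
        counts = simulate_counts(gene, [iso], 100, seed=5)
        selected, fits = quantify_gene(g, counts)
        assert {i.exons for i in selected.isoform_set} == {(0, 1, 2)}
        assert selected.isoform_set.isoforms[0].abundance == pytest.approx(5.0, rel=0.05)

    def test_small_lambda_approaches_unpenalized_optimum(self):
        """As the penalty vanishes the refit log-likelihood of the best
        support approaches the path-space optimum."""
        gene, isoforms, graph = study_instance(expected_reads=2e3)
        counts = simulate_counts(gene, isoforms, graph.read_length, seed=9)
        obj0, _ = path_space_solve(graph, counts, 1e-8)
        fits = fit_path(graph, counts, FitConfig())
        from isoflow import poisson_loglik
        from scipy.special import gammaln

        # compare on the same scale: drop constants from the refit value
        const = float(gammaln(counts.counts + 1).sum())
        best = max(f.loglik + const for f in fits)
        assert -best <= obj0 + 1e-3 * max(1.0, abs(obj0))

    def test_two_isoform_recovery_single_replicate(self):
        gene, isoforms, graph = study_instance()
        counts = simulate_counts(gene, isoforms, graph.read_length, seed=12)
        selected, _ = quantify_gene(graph, counts)
        assert {i.exons for i in selected.isoform_set} == {i.exons for i in isoforms}
        truth = {i.exons: i.abundance for i in isoforms}
        for iso in selected.isoform_set:
            assert iso.abundance == pytest.approx(truth[iso.exons], rel=0.05)


def test_fit_config_grid_validation():
    with pytest.raises(ValueError):
        FitConfig(lambda_grid=[1.0, 2.0]).grid_for(
            BinCounts((), np.zeros(0), 50)
        )
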