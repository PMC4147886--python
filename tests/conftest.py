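"""Shared fixtures: the five-exon illustration gene and random instances."""

from __future__ import annotations

import random

import numpy as np
import pytest

from isoflow import (
    BinCounts,
    GeneModel,
    Isoform,
    build_graph,
    junctions_from_isoforms,
)

#: Read length used by the five-exon worked example.
FIG_L = 100

#: Splicing-graph junctions of the worked example (0-based exon indices):
#: 1->2, 1->4, 2->3, 3->4, 3->5, 4->5 in 1-based figure numbering.
FIG_JUNCTIONS = {(0, 1), (0, 3), (1, 2), (2, 3), (2, 4), (3, 4)}


@pytest.fixture(scope="session")
def fig_gene() -> GeneModel:
    """Five exons, all longer than the read, so bins are exons and
    exon-exon junctions."""
    return GeneModel.from_lengths([200] * 5, gene_id="fig")


@pytest.fixture(scope="session")
def fig_graph(fig_gene):
    return build_graph(fig_gene, FIG_JUNCTIONS, FIG_L)


@pytest.fixture(scope="session")
def short_exon_gene() -> GeneModel:
    """Same junctions but exon 3 (index 2) shorter than the read, so bins
    with three exons appear."""
    return GeneModel.from_lengths([200, 200, 50, 200, 200], gene_id="fig-short")


@pytest.fixture(scope="session")
def short_exon_graph(short_exon_gene):
    return build_graph(short_exon_gene, FIG_JUNCTIONS, FIG_L)


def random_instance(rng: random.Random, max_exons: int = 6, L: int = 50):
    """A random small gene, junction set and bin graph."""
    n = rng.randint(2, max_exons)
    lengths = [rng.randint(20, 3 * L) for _ in range(n)]
    all_j = [(i, j) for i in range(n) for j in range(i + 1, n)]
    junctions = set(rng.sample(all_j, rng.randint(1, len(all_j))))
    gene = GeneModel.from_lengths(lengths)
    return gene, junctions, build_graph(gene, junctions, L)


def random_counts(graph, nprng: np.random.Generator, mean: float = 30.0) -> BinCounts:
    bins = tuple(graph.bins)
    y = nprng.poisson(mean, size=len(bins)).astype(float)
    return BinCounts(bins, y, graph.read_length)


# --- canonical two-isoform recovery study -------------------------------

#: Mutually-exclusive-exon gene: the major isoform uses exons 1, 2 and 4,
#: the minor isoform the long exclusive exon 3; flanking exons shared.
STUDY_LENGTHS = [200, 150, 150, 500, 150, 200]
STUDY_MAJOR = (0, 1, 2, 4, 5)
STUDY_MINOR = (0, 3, 5)
STUDY_L = 150
STUDY_RATIO = 3.0
STUDY_READS = 1e4


def study_instance(expected_reads: float = STUDY_READS):
    """Gene, true isoforms (3:1) and graph of the recovery study, with
    abundances scaled to the requested expected total read count."""
    gene = GeneModel.from_lengths(STUDY_LENGTHS, gene_id="study")
    lens = gene.exon_lengths
    len_major = sum(lens[i] for i in STUDY_MAJOR)
    len_minor = sum(lens[i] for i in STUDY_MINOR)
    unit = expected_reads / (
        STUDY_RATIO * (len_major - STUDY_L + 1) + (len_minor - STUDY_L + 1)
    )
    isoforms = [
        Isoform(STUDY_MAJOR, STUDY_RATIO * unit),
        Isoform(STUDY_MINOR, unit),
    ]
    graph = build_graph(gene, junctions_from_isoforms(isoforms), STUDY_L)
    return gene, isoforms, graph
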