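"""Synthetic RNA-Seq data generated under the package's own Poisson model.

Two levels of fidelity:

* :func:`simulate_counts` draws per-bin read counts directly from the
  Poisson model (bin count ~ Poisson(l_v * sum of abundances of the
  isoforms containing the bin)), for solver and recovery tests.
* :func:`simulate_reads` places individual error-free single-end reads
  uniformly over the admissible start positions of each isoform (isoform
  chosen proportionally to theta_j * (length_j - L + 1)), and can emit
  them as SAM alignments with N CIGAR operations across introns, to
  exercise the alignment-ingestion path.

Reads are error-free and perfectly mapped: the generator's job is to
satisfy the model's own assumptions so that recovery tests measure the
estimator, not alignment artifacts.  Positional or sequence bias is not
modeled.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gene_model import Bin, GeneModel, Isoform, isoform_bins, _window_exons
from .objective import BinCounts


@dataclass(frozen=True)
class ReadPlacement:
    """A simulated read: which isoform it came from and its start offset
    in that isoform's concatenated-exon (transcript) coordinates."""

    isoform_index: int
    offset: int


def junctions_from_isoforms(isoforms: Sequence[Isoform]) -> set[tuple[int, int]]:
    """Exon junction pairs used by a set of isoforms."""
    out: set[tuple[int, int]] = set()
    for iso in isoforms:
        out.update(zip(iso.exons, iso.exons[1:]))
    return out


def expected_bin_intensities(
    gene: GeneModel, isoforms: Sequence[Isoform], read_length: int
) -> dict[tuple[int, ...], float]:
    """delta_v = l_v * sum over isoforms containing bin v of theta_j, over
    the union of the isoforms' bins."""
    delta: dict[tuple[int, ...], float] = {}
    eff: dict[tuple[int, ...], int] = {}
    for iso in isoforms:
        for b in isoform_bins(iso, gene, read_length):
            eff[b.exons] = b.effective_length
            delta[b.exons] = delta.get(b.exons, 0.0) + b.effective_length * iso.abundance
    return delta


def simulate_counts(
    gene: GeneModel,
    isoforms: Sequence[Isoform],
    read_length: int,
    seed: int,
) -> BinCounts:
    """Draw per-bin counts y_v ~ Poisson(delta_v); deterministic given seed."""
    rng = np.random.default_rng(seed)
    delta = expected_bin_intensities(gene, isoforms, read_length)
    keys = sorted(delta)
    eff = {
        b.exons: b.effective_length
        for iso in isoforms
        for b in isoform_bins(iso, gene, read_length)
    }
    bins = tuple(Bin(k, eff[k]) for k in keys)
    counts = rng.poisson([delta[k] for k in keys]).astype(float)
    return BinCounts(bins, counts, read_length, gene_id=gene.gene_id)


def simulate_reads(
    gene: GeneModel,
    isoforms: Sequence[Isoform],
    read_length: int,
    n_reads: int,
    seed: int,
) -> list[ReadPlacement]:
    """Place n_reads error-free reads on the isoforms.

    The isoform of each read is chosen with probability proportional to
    theta_j * (length_j - L + 1); the start offset is uniform over the
    admissible positions.  Every isoform must be at least L long.
    """
    L = int(read_length)
    lengths = [iso.length(gene) for iso in isoforms]
    if any(ln < L for ln in lengths):
        raise ValueError("every isoform must be at least as long as the read")
    weights = np.array(
        [iso.abundance * (ln - L + 1) for iso, ln in zip(isoforms, lengths)], dtype=float
    )
    rng = np.random.default_rng(seed)
    if n_reads == 0 or weights.sum() <= 0:
        return []
    p = weights / weights.sum()
    choice = rng.choice(len(isoforms), size=n_reads, p=p)
    out: list[ReadPlacement] = []
    for j in choice:
        offset = int(rng.integers(0, lengths[j] - L + 1))
        out.append(ReadPlacement(int(j), offset))
    return out


def bin_reads(
    gene: GeneModel,
    isoforms: Sequence[Isoform],
    placements: Sequence[ReadPlacement],
    read_length: int,
) -> BinCounts:
    """Assign simulated reads to bins by their transcript coordinates."""
    L = int(read_length)
    counts: dict[tuple[int, ...], float] = {}
    eff: dict[tuple[int, ...], int] = {}
    cums = []
    for iso in isoforms:
        lens = [gene.exons[i].length for i in iso.exons]
        cum = [0]
        for ln in lens:
            cum.append(cum[-1] + ln)
        cums.append(cum)
    for rp in placements:
        iso = isoforms[rp.isoform_index]
        cum = cums[rp.isoform_index]
        first, last = _window_exons(cum, rp.offset, L)
        key = tuple(iso.exons[first : last + 1])
        counts[key] = counts.get(key, 0.0) + 1.0
    for iso in isoforms:
        for b in isoform_bins(iso, gene, read_length):
            eff[b.exons] = b.effective_length
    keys = sorted(counts)
    bins = tuple(Bin(k, eff.get(k, 0)) for k in keys)
    return BinCounts(bins, np.array([counts[k] for k in keys]), L, gene_id=gene.gene_id)


def read_genomic_blocks(
    gene: GeneModel, isoform: Isoform, offset: int, read_length: int
) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks covered by a read at a transcript
    offset; consecutive exons contiguous in the genome are merged."""
    L = int(read_length)
    blocks: list[tuple[int, int]] = []
    remaining = L
    pos = offset
    cum = 0
    for i in isoform.exons:
        e = gene.exons[i]
        if pos >= cum + e.length:
            cum += e.length
            continue
        within = pos - cum
        take = min(remaining, e.length - within)
        start = e.start + within
        blocks.append((start, start + take))
        remaining -= take
        pos += take
        cum += e.length
        if remaining == 0:
            break
    if remaining != 0:
        raise ValueError("read extends past the end of the isoform")
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        if s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged
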