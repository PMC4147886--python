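"""Gene models, read bins and effective lengths.

A gene is an ordered list of non-overlapping exons on one strand.  Exons
with alternative donor/acceptor sites are assumed to have been pre-split
into disjoint "atomic" exons at annotation load, so every isoform of the
gene is a strictly increasing chain of exon indices.

A *bin* is the exact ordered set of exons that a read overlaps; it is the
unit at which reads are counted.  The *effective length* of a bin is the
number of read start positions (in any isoform containing the bin) that
assign a read to that bin; it does not depend on the containing isoform.

Coordinates are 0-based half-open throughout this package; conversion
happens only at GTF (1-based inclusive) and BED boundaries.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon interval, 0-based half-open."""

    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty exon [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Ordered, non-overlapping exons of one gene on one strand."""

    gene_id: str
    exons: tuple[Exon, ...]
    chrom: str = "chr"
    strand: str = "+"

    def __post_init__(self) -> None:
        exons = tuple(
            e if e.index == i else Exon(e.start, e.end, i)
            for i, e in enumerate(self.exons)
        )
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )

    @classmethod
    def from_lengths(
        cls,
        lengths: Sequence[int],
        gene_id: str = "gene",
        gap: int = 100,
        origin: int = 0,
        chrom: str = "chr",
        strand: str = "+",
    ) -> "GeneModel":
        """Build a gene from exon lengths, separated by fixed intron gaps."""
        exons = []
        pos = origin
        for i, ln in enumerate(lengths):
            exons.append(Exon(pos, pos + ln, i))
            pos += ln + gap
        return cls(gene_id, tuple(exons), chrom=chrom, strand=strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e.length for e in self.exons)


@dataclass(frozen=True, order=True)
class Bin:
    """An ordered set of exons together with its effective length."""

    exons: tuple[int, ...]
    effective_length: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("bin must contain at least one exon")
        if any(b <= a for a, b in zip(self.exons, self.exons[1:])):
            raise ValueError(f"bin exons must be strictly increasing: {self.exons}")


@dataclass(frozen=True)
class Isoform:
    """A transcript: a strictly increasing chain of exon indices with an
    abundance theta expressed in expected reads per base."""

    exons: tuple[int, ...]
    abundance: float = 0.0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("isoform must contain at least one exon")
        if any(b <= a for a, b in zip(self.exons, self.exons[1:])):
            raise ValueError(f"isoform exons must be strictly increasing: {self.exons}")
        if not (self.abundance >= 0.0 and self.abundance < float("inf")):
            raise ValueError(f"abundance must be finite and >= 0: {self.abundance}")

    def length(self, gene: GeneModel) -> int:
        return sum(gene.exons[i].length for i in self.exons)


def effective_length(bin_exon_lengths: Sequence[int], read_length: int) -> int:
    """Number of admissible read start positions for a bin.

    For a single exon of length l_e the count is l_e - L + 1.  For k >= 2
    exons with leftmost/rightmost lengths l_left, l_right and total internal
    length l_int (zero when k = 2),

        min(l_left, L - l_int - 1) + min(l_right, L - l_int - 1) - L + l_int + 1.

    Negative values are clamped to zero (the bin admits no read).
    """
    if len(bin_exon_lengths) == 0:
        raise ValueError("bin must contain at least one exon")
    L = int(read_length)
    if L < 1:
        raise ValueError(f"read length must be >= 1, got {read_length}")
    lengths = [int(x) for x in bin_exon_lengths]
    if any(x < 1 for x in lengths):
        raise ValueError("exon lengths must be >= 1")
    if len(lengths) == 1:
        return max(0, lengths[0] - L + 1)
    l_left, l_right = lengths[0], lengths[-1]
    l_int = sum(lengths[1:-1])
    value = (
        min(l_left, L - l_int - 1)
        + min(l_right, L - l_int - 1)
        - L
        + l_int
        + 1
    )
    return max(0, value)


def _window_exons(cum: Sequence[int], start: int, read_length: int) -> tuple[int, int]:
    """Indices (first, last) of the exons overlapped by a read placed at
    transcript offset `start`, given cumulative exon lengths `cum`."""
    first = bisect_right(cum, start) - 1
    last = bisect_right(cum, start + read_length - 1) - 1
    return first, last


def isoform_bins(
    isoform: Isoform, gene: GeneModel, read_length: int
) -> list[Bin]:
    """Ordered sequence of bins produced by sliding a read along an isoform.

    Slides a window of `read_length` bases over the isoform's concatenated
    exons and records each distinct set of overlapped exons in order of
    first occurrence.  Returns the empty list (with a warning) when the
    isoform is shorter than the read.
    """
    n = gene.n_exons
    if any(i < 0 or i >= n for i in isoform.exons):
        raise ValueError(
            f"isoform exon indices {isoform.exons} out of range for "
            f"gene with {n} exons"
        )
    lengths = [gene.exons[i].length for i in isoform.exons]
    total = sum(lengths)
    L = int(read_length)
    if total < L:
        warnings.warn(
            f"isoform {isoform.exons} of length {total} is shorter than the "
            f"read length {L}; no bins produced",
            stacklevel=2,
        )
        return []
    cum = [0]
    for ln in lengths:
        cum.append(cum[-1] + ln)
    bins: list[Bin] = []
    p = 0
    while p <= total - L:
        first, last = _window_exons(cum, p, L)
        exon_ids = tuple(isoform.exons[first : last + 1])
        bins.append(
            Bin(exon_ids, effective_length([lengths[j] for j in range(first, last + 1)], L))
        )
        # next start at which the overlapped exon set changes
        p_next = min(cum[first + 1], cum[last + 1] - L + 1)
        p = max(p + 1, p_next)
    return bins
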