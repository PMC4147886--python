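"""Transcript matching and precision/recall.

A truth transcript counts as detected when some prediction has the same
exon chain with identical internal boundary coordinates; the start of the
first exon and the end of the last exon are free, since read-based
methods cannot pin down transcript ends exactly.  Single-exon transcripts
have no internal boundaries and are matched by genomic overlap instead.
Matching is greedy and one-to-one: each prediction can account for at
most one truth transcript.  Precision and recall can be stratified by the
number of annotated transcripts of the gene (deconvolution difficulty
grows with it) or by exon count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class Transcript:
    """A transcript in genomic coordinates (0-based half-open exons)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    abundance: float = 0.0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"unsorted/overlapping exons in {self.transcript_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def internal_signature(self) -> tuple:
        """All exon boundary coordinates except the outermost two."""
        coords: list[int] = []
        for s, e in self.exons:
            coords += [s, e]
        return (self.chrom, self.strand, self.n_exons, tuple(coords[1:-1]))


@dataclass
class MatchTable:
    """Outcome of greedy one-to-one matching."""

    predictions: pd.DataFrame  # transcript_id, gene_id, matched_truth
    truths: pd.DataFrame  # transcript_id, gene_id, detected

    @property
    def n_matched(self) -> int:
        return int(self.truths["detected"].sum())


def match_transcripts(
    predicted: Sequence[Transcript], truth: Sequence[Transcript]
) -> MatchTable:
    """Greedy one-to-one matching of predictions to truth transcripts."""
    unmatched: dict[tuple, list[int]] = {}
    singles: list[int] = []
    for i, t in enumerate(truth):
        if t.n_exons == 1:
            singles.append(i)
        else:
            unmatched.setdefault(t.internal_signature(), []).append(i)
    matched_truth: list[Optional[str]] = []
    detected = [False] * len(truth)
    taken_singles: set[int] = set()
    for p in predicted:
        hit: Optional[int] = None
        if p.n_exons == 1:
            ps, pe = p.span
            for i in singles:
                t = truth[i]
                if i in taken_singles or t.chrom != p.chrom or t.strand != p.strand:
                    continue
                ts, te = t.span
                if ps < te and ts < pe:  # genomic overlap
                    hit = i
                    taken_singles.add(i)
                    break
        else:
            cands = unmatched.get(p.internal_signature())
            if cands:
                hit = cands.pop(0)
        if hit is not None:
            detected[hit] = True
            matched_truth.append(truth[hit].transcript_id)
        else:
            matched_truth.append(None)
    preds_df = pd.DataFrame(
        {
            "transcript_id": [p.transcript_id for p in predicted],
            "gene_id": [p.gene_id for p in predicted],
            "matched_truth": matched_truth,
        }
    )
    truth_df = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in truth],
            "gene_id": [t.gene_id for t in truth],
            "n_exons": [t.n_exons for t in truth],
            "detected": detected,
        }
    )
    return MatchTable(preds_df, truth_df)


def precision_recall(
    table: MatchTable, stratify_by: str = "transcripts"
) -> pd.DataFrame:
    """Per-stratum precision and recall, plus a pooled 'all' row.

    stratify_by: 'transcripts' groups genes by their number of truth
    transcripts; 'exons' groups truth transcripts by exon count.
    Predictions are assigned to strata through their gene_id; empty
    strata report NaN.
    """
    preds, truths = table.predictions, table.truths
    rows = []

    def pr(n_pred: int, n_match: int, n_truth: int, n_det: int) -> tuple:
        precision = n_match / n_pred if n_pred else float("nan")
        recall = n_det / n_truth if n_truth else float("nan")
        return precision, recall

    if stratify_by == "transcripts":
        gene_sizes = truths.groupby("gene_id").size()
        strata = sorted(gene_sizes.unique())
        for st in strata:
            genes = set(gene_sizes[gene_sizes == st].index)
            p_sub = preds[preds["gene_id"].isin(genes)]
            t_sub = truths[truths["gene_id"].isin(genes)]
            precision, recall = pr(
                len(p_sub),
                int(p_sub["matched_truth"].notna().sum()),
                len(t_sub),
                int(t_sub["detected"].sum()),
            )
            rows.append((str(st), len(p_sub), len(t_sub), precision, recall))
    elif stratify_by == "exons":
        for st in sorted(truths["n_exons"].unique()):
            t_sub = truths[truths["n_exons"] == st]
            genes = set(t_sub["gene_id"])
            p_sub = preds[preds["gene_id"].isin(genes)]
            precision, recall = pr(
                len(p_sub),
                int(p_sub["matched_truth"].notna().sum()),
                len(t_sub),
                int(t_sub["detected"].sum()),
            )
            rows.append((str(st), len(p_sub), len(t_sub), precision, recall))
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")

    precision, recall = pr(
        len(preds),
        int(preds["matched_truth"].notna().sum()),
        len(truths),
        int(truths["detected"].sum()),
    )
    rows.append(("all", len(preds), len(truths), precision, recall))
    return pd.DataFrame(
        rows, columns=["stratum", "n_predictions", "n_truth", "precision", "recall"]
    )
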