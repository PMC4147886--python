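"""Standard-format ingestion and emission: GTF, BED, SAM, bin-count TSV.

Internal coordinates are 0-based half-open; GTF records (1-based,
inclusive) and BED records (0-based half-open) are converted at the
boundary.  At annotation load, exons of one gene coming from different
transcripts are split at every alternative donor/acceptor boundary into
disjoint "atomic" exons, so that every transcript becomes a strictly
increasing chain of atomic exon indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

from .evaluation import Transcript
from .gene_model import Bin, Exon, GeneModel, Isoform
from .objective import BinCounts
from .simulator import ReadPlacement, read_genomic_blocks

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GTF / BED reading

def read_gtf_transcripts(path: str | Path) -> list[Transcript]:
    """All transcripts of a GTF file as genomic exon chains."""
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    grouped: dict[str, dict] = {}
    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = f.attributes["transcript_id"][0]
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": f.attributes["gene_id"][0],
                "chrom": f.seqid,
                "strand": f.strand if f.strand in "+-" else "+",
                "exons": [],
                "abundance": 0.0,
            },
        )
        rec["exons"].append((f.start - 1, f.end))  # GTF is 1-based inclusive
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        if tid in grouped and "abundance" in f.attributes:
            grouped[tid]["abundance"] = float(f.attributes["abundance"][0])
    out = []
    for tid, rec in grouped.items():
        exons = tuple(sorted(rec["exons"]))
        out.append(
            Transcript(
                tid, rec["gene_id"], rec["chrom"], rec["strand"], exons, rec["abundance"]
            )
        )
    out.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return out


def read_bed12_transcripts(path: str | Path) -> list[Transcript]:
    """Transcripts from a BED12 file (blocks become exons)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns")
            chrom, start, _end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if parts[5] in "+-" else "+"
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + sz) for off, sz in zip(starts, sizes)
            )
            out.append(Transcript(name, name, chrom, strand, exons))
    return out


def read_bed6_junctions(path: str | Path) -> list[tuple[str, int, int]]:
    """Splice junctions from a BED6 file as (chrom, donor_end, acceptor_start):
    the interval is taken to span the intron (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED requires at least 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# Gene models from transcripts (atomic exon splitting)

@dataclass
class GeneAnnotation:
    """One gene's atomic-exon model plus its annotated transcript chains."""

    gene: GeneModel
    transcript_chains: dict[str, tuple[int, ...]]

    def chain_of(self, transcript_id: str) -> tuple[int, ...]:
        return self.transcript_chains[transcript_id]


def gene_models_from_transcripts(
    transcripts: Sequence[Transcript],
) -> dict[str, GeneAnnotation]:
    """Group transcripts by gene and split exons at every alternative
    boundary, producing atomic exons (e.g. an exon with two alternative
    donor sites becomes one exon ending at the first site and a second
    from there to the next site)."""
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out: dict[str, GeneAnnotation] = {}
    for gene_id, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes: {chroms}")
        boundaries: set[int] = set()
        for t in ts:
            for s, e in t.exons:
                boundaries.update((s, e))
        cuts = sorted(boundaries)
        # atomic segments: [cut_i, cut_{i+1}) covered by at least one exon
        segments = []
        for a, b in zip(cuts, cuts[1:]):
            if any(s <= a and b <= e for t in ts for s, e in t.exons):
                segments.append((a, b))
        exons = tuple(Exon(s, e, i) for i, (s, e) in enumerate(segments))
        gene = GeneModel(gene_id, exons, chrom=ts[0].chrom, strand=sorted(strands)[0])
        seg_index = {seg: i for i, seg in enumerate(segments)}
        chains: dict[str, tuple[int, ...]] = {}
        for t in ts:
            chain: list[int] = []
            for s, e in t.exons:
                for seg, i in seg_index.items():
                    if s <= seg[0] and seg[1] <= e:
                        chain.append(i)
            chains[t.transcript_id] = tuple(sorted(chain))
        out[gene_id] = GeneAnnotation(gene, chains)
    return out


def isoform_to_transcript(
    gene: GeneModel,
    isoform: Isoform,
    transcript_id: str,
) -> Transcript:
    """Genomic transcript for an atomic-exon chain; adjacent atomic exons
    that are contiguous in the genome are merged back into single exons."""
    blocks: list[tuple[int, int]] = []
    for i in isoform.exons:
        e = gene.exons[i]
        if blocks and blocks[-1][1] == e.start:
            blocks[-1] = (blocks[-1][0], e.end)
        else:
            blocks.append((e.start, e.end))
    return Transcript(
        transcript_id,
        gene.gene_id,
        gene.chrom,
        gene.strand,
        tuple(blocks),
        abundance=isoform.abundance,
    )


# ---------------------------------------------------------------------------
# De novo exon detection (coverage clusters)

def detect_genes_from_sam(path: str | Path) -> list[GeneModel]:
    """Simple coverage-cluster exon detector for annotation-free mode.

    Contiguous read-covered regions (union of aligned blocks) form gene
    loci; within each locus, exons are split at every junction boundary
    observed in spliced (N CIGAR) alignments.  No transcription start or
    polyadenylation sites are modeled.
    """
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    cuts_by_chrom: dict[str, set[int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            blocks = read.get_blocks()
            if not blocks:
                continue
            chrom = read.reference_name
            blocks_by_chrom.setdefault(chrom, []).extend(blocks)
            cuts = cuts_by_chrom.setdefault(chrom, set())
            for (a, b), (c, d) in zip(blocks, blocks[1:]):
                cuts.update((b, c))  # donor end, acceptor start
    genes: list[GeneModel] = []
    for chrom in sorted(blocks_by_chrom):
        merged: list[list[int]] = []
        for s, e in sorted(blocks_by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cuts = cuts_by_chrom.get(chrom, set())
        for gi, (s, e) in enumerate(merged):
            inner = sorted(c for c in cuts if s < c < e)
            bounds = [s] + inner + [e]
            exons = tuple(
                Exon(a, b, i) for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
            )
            genes.append(
                GeneModel(f"{chrom}:{s}-{e}", exons, chrom=chrom, strand="+")
            )
    return genes


# ---------------------------------------------------------------------------
# GTF writing

def write_gtf(
    path: str | Path,
    transcripts: Sequence[Transcript],
    total_mapped_reads: Optional[float] = None,
    source: str = "isoflow",
) -> None:
    """One `transcript` plus per-exon `exon` records per transcript.

    Attributes carry the abundance theta (reads per base) and, when the
    total number of mapped reads is known, FPKM = theta * 1e9 / total.
    """
    lines = ["##format: gtf"]
    for t in transcripts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        attrs += f' abundance "{t.abundance:.6g}";'
        if total_mapped_reads and total_mapped_reads > 0:
            fpkm = t.abundance * 1e9 / total_mapped_reads
            attrs += f' FPKM "{fpkm:.6g}";'
        s, e = t.span
        lines.append(
            "\t".join(
                [t.chrom, source, "transcript", str(s + 1), str(e), ".", t.strand, ".", attrs]
            )
        )
        for s, e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, source, "exon", str(s + 1), str(e), ".", t.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SAM reading / writing

def sam_to_bin_counts(
    path: str | Path,
    gene: GeneModel,
    read_length: Optional[int] = None,
) -> tuple[BinCounts, set[tuple[int, int]], dict]:
    """Assign each mapped single-end read to the bin of exons it overlaps.

    A read is retained when its aligned blocks tile a contiguous window of
    some chain of the gene's exons (block edges coinciding with exon
    boundaries); junction evidence is harvested from the consecutive exon
    pairs of every retained read.  Reads overlapping no exon, or
    overhanging exon boundaries inconsistently, are discarded and counted
    in the diagnostics.
    """
    exon_list = gene.exons
    starts = [e.start for e in exon_list]
    ends = [e.end for e in exon_list]
    counts: dict[tuple[int, ...], float] = {}
    junctions: set[tuple[int, int]] = set()
    diagnostics = {"retained": 0, "outside_exons": 0, "boundary_mismatch": 0, "unmapped": 0}
    lengths_seen: list[int] = []

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != gene.chrom:
                diagnostics["unmapped"] += 1
                continue
            blocks = read.get_blocks()
            if not blocks:
                diagnostics["unmapped"] += 1
                continue
            touched: list[int] = []
            for bs, be in blocks:
                for i, e in enumerate(exon_list):
                    if bs < e.end and e.start < be:
                        if not touched or touched[-1] != i:
                            touched.append(i)
            if not touched:
                diagnostics["outside_exons"] += 1
                continue
            if sorted(set(touched)) != touched:
                diagnostics["boundary_mismatch"] += 1
                continue
            # verify the read tiles a contiguous transcript window of the
            # touched exon chain exactly
            chain = touched
            expected: list[tuple[int, int]] = []
            for idx, i in enumerate(chain):
                e = exon_list[i]
                lo = max(e.start, blocks[0][0]) if idx == 0 else e.start
                hi = min(e.end, blocks[-1][1]) if idx == len(chain) - 1 else e.end
                if lo >= hi:
                    break
                if expected and expected[-1][1] == lo:
                    expected[-1] = (expected[-1][0], hi)
                else:
                    expected.append((lo, hi))
            if expected != list(blocks):
                diagnostics["boundary_mismatch"] += 1
                continue
            key = tuple(chain)
            counts[key] = counts.get(key, 0.0) + 1.0
            junctions.update(zip(chain, chain[1:]))
            diagnostics["retained"] += 1
            if len(lengths_seen) < 1000:
                lengths_seen.append(read.query_length or read.infer_query_length() or 0)

    if read_length is None:
        if not lengths_seen:
            raise ValueError("cannot infer read length from an empty SAM file")
        read_length = int(np.bincount(lengths_seen).argmax())
        logger.info("inferred read length %d from %d reads", read_length, len(lengths_seen))

    from .gene_model import effective_length  # local import to avoid cycle

    keys = sorted(counts)
    gl = gene.exon_lengths
    bins = tuple(
        Bin(k, effective_length([gl[i] for i in k], read_length)) for k in keys
    )
    y = np.array([counts[k] for k in keys])
    return BinCounts(bins, y, read_length, gene_id=gene.gene_id), junctions, diagnostics


def write_sam_reads(
    path: str | Path,
    gene: GeneModel,
    isoforms: Sequence[Isoform],
    placements: Sequence[ReadPlacement],
    read_length: int,
    chrom_length: Optional[int] = None,
) -> None:
    """Emit simulated reads as a text SAM file with M/N CIGAR operations."""
    write_sam_reads_multi(
        path,
        [(gene, isoforms, placements)],
        read_length,
        chrom_lengths={gene.chrom: chrom_length} if chrom_length else None,
    )


def write_sam_reads_multi(
    path: str | Path,
    per_gene: Sequence[tuple[GeneModel, Sequence[Isoform], Sequence[ReadPlacement]]],
    read_length: int,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> None:
    """SAM emission for several genes sharing one file (one @SQ per chrom)."""
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for gene, _, _ in per_gene:
        need = gene.exons[-1].end + 1000
        lengths[gene.chrom] = max(lengths.get(gene.chrom, 0) or 0, need)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for gene, isoforms, placements in per_gene:
            tid = out.get_tid(gene.chrom)
            for r, rp in enumerate(placements):
                blocks = read_genomic_blocks(
                    gene, isoforms[rp.isoform_index], rp.offset, read_length
                )
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{gene.gene_id}_r{r}"
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.flag = 0
                a.reference_id = tid
                a.reference_start = blocks[0][0]
                a.mapping_quality = 60
                cigar = []
                for k, (s, e) in enumerate(blocks):
                    if k > 0:
                        cigar.append((3, s - blocks[k - 1][1]))  # N
                    cigar.append((0, e - s))  # M
                a.cigartuples = cigar
                out.write(a)


# ---------------------------------------------------------------------------
# Bin-count TSV dialect

def write_bin_counts_tsv(path: str | Path, counts: BinCounts) -> None:
    """Columns gene_id, exon_ids (comma-joined 0-based), count."""
    df = pd.DataFrame(
        {
            "gene_id": [counts.gene_id] * counts.q,
            "exon_ids": [",".join(map(str, b.exons)) for b in counts.bins],
            "count": counts.counts.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts_tsv(
    path: str | Path, gene: GeneModel, read_length: int
) -> BinCounts:
    from .gene_model import effective_length

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "exon_ids", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"bin-count TSV must have columns {sorted(required)}")
    df = df[df["gene_id"] == gene.gene_id]
    gl = gene.exon_lengths
    bins = []
    for s in df["exon_ids"]:
        k = tuple(int(x) for x in str(s).split(","))
        bins.append(Bin(k, effective_length([gl[i] for i in k], read_length)))
    return BinCounts(
        tuple(bins),
        df["count"].to_numpy(dtype=float),
        read_length,
        gene_id=gene.gene_id,
    )
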