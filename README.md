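# isoflow

Joint identification and quantification of RNA isoforms from single-end
RNA-Seq alignments, for transcriptomics analysts who want *de novo*
transcript discovery that uses read density — without enumerating the
exponentially many candidate transcripts of a multi-exon gene.

## The method

Reads are counted per **bin** — the exact ordered set of exons a read
overlaps — and bin counts are modeled as independent Poisson variables,
`y_i ~ Poisson(l_i Σ_j U_ji θ_j)`, where `l_i` is the bin's effective
length (number of read start positions assigning a read to it), `θ_j ≥ 0`
the abundance of candidate isoform `j` in reads per base, and `U` the
bin/isoform incidence.  Isoforms are selected and quantified jointly by
the ℓ1-penalized maximum-likelihood estimator

```
minimize over θ ≥ 0:   Σ_i [δ_i − y_i log δ_i]  +  λ ‖θ‖₁ ,
                       δ_i = l_i Σ_j U_ji θ_j
```

over **all** candidate isoforms at once.  The key device is a DAG over
the positive-effective-length bins whose (s,t)-paths are in bijection
with candidate isoforms: the objective becomes a separable convex cost
of a network **flow** on that graph (the ℓ1 term is λ × flow into the
sink), with only as many variables as arcs.  The optimal flow is decoded
into isoforms by iteratively extracting the maximum-bottleneck (s,t)-path,
and the regularization parameter is chosen by BIC after an unpenalized
refit of each candidate support.  See `docs/methods.md` for the details
and design decisions.

## Worked example

A six-exon gene with two isoforms in a 3:1 abundance ratio — the major
isoform through exons 0-1-2-4-5, the minor one through the long
mutually-exclusive exon 3 — simulated under the package's own Poisson
model and quantified back:

```python
from isoflow import (GeneModel, Isoform, build_graph, simulate_counts,
                     junctions_from_isoforms, quantify_gene)

gene = GeneModel.from_lengths([200, 150, 150, 500, 150, 200], gene_id="demo")
truth = [Isoform((0, 1, 2, 4, 5), 6.0), Isoform((0, 3, 5), 2.0)]
graph = build_graph(gene, junctions_from_isoforms(truth), read_length=150)
counts = simulate_counts(gene, truth, read_length=150, seed=7)
print(f"{counts.q} bins, {int(counts.total)} reads")
selected, path = quantify_gene(graph, counts)
print(f"selected lambda = {selected.lam:.3g}, BIC = {selected.bic:.2f}")
for iso in selected.isoform_set:
    print(f"isoform {'-'.join(map(str, iso.exons))}: {iso.abundance:.3f} reads/base")
```

prints

```
12 bins, 5673 reads
selected lambda = 5.67e+03, BIC = -55.42
isoform 0-1-2-4-5: 5.965 reads/base
isoform 0-3-5: 1.987 reads/base
```

Both true exon chains are recovered exactly and the refit abundances
(reads per base) are within about 1% of the simulated 6.0 and 2.0 —
consistent with the ≈1–2% Poisson standard error at this depth.

The same pipeline is available from the shell:

```sh
isoflow simulate --gene-spec panel.tsv --n-reads 50000 --read-length 100 \
                 --seed 11 --out reads.sam --truth truth.gtf
isoflow quantify --sam reads.sam --annotation truth.gtf --read-length 100 \
                 --out pred.gtf
isoflow eval     --pred pred.gtf --truth truth.gtf --out pr.tsv
```

`quantify` also runs annotation-free with `--de-novo` (exons detected as
coverage clusters split at observed junctions).  Predictions are written
as GTF with `abundance` (reads/base) and `FPKM` attributes; `eval`
applies the exact-internal-boundary matching protocol and reports
precision/recall stratified by transcripts per gene.

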