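# transqc

Post-assembly quality control for *de novo* transcriptome assemblies.

Short-read assemblers (Oases, Trinity, Trans-ABySS, SOAPdenovo-Trans) emit
redundant isoform sets and a non-trivial fraction of **chimeric transcripts**
— sequences stitched together from more than one true transcript region, by
misassembly, PCR recombination, or genuine fusion/trans-splicing.  For
phylogenomics, where one correct representative per gene is wanted, both
problems have to be cleaned up after assembly.  `transqc` implements that
cleanup as a library and CLI, plus a deterministic synthetic-data generator
with known ground truth to benchmark it.

## What it computes

**Chimera taxonomy.** A chimera's two components can come from the same gene
(*self*) or different genes (*multi-gene*), and can be joined in the same
orientation (*cis*) or opposite orientations (*trans*) — four types:
cis-self, cis-multi-gene, trans-self, trans-multi-gene.

**Reference-based detection** (`eval-ref`). Transcripts are aligned to a
reference transcript set (BLAT, PSL). Hits with identity < 95% or fewer than
100 matching bases are ignored. A single-hit query is non-chimeric. For a
multi-hit query the hit with the most matching bases is the *best hit*; the
query is a chimera if any other hit's query coverage has *no, or minimal,
overlap* with the best hit's:

```
overlap < 60 bp   AND   overlap < 0.20 × min(|q_best|, |q_other|)
```

The chimera type follows from whether the two hits share a target and a
strand. The same module computes the assembly report: per reference gene,
the longest coverage by a best hit of a non-chimeric query; from these, the
percent of reference bp assembled (> 200 bp), percent of genes assembled
> 200 bp, percent of genes assembled to ≥ 80% of their length, the chimera
rate, and redundancy = (queries with hits) / (references with hits).

**Reference-free trans-chimera removal** (`clean-trans`). From translated
(blastx-style) hits against model proteins: HSPs with identity < 30% or
query coverage < 100 bp are ignored; same-direction query coverages are
merged into one span per reading direction ("one ORF per direction"); if the
plus and minus spans of a query–target pair pass the minimal-overlap rule
above, the query is a trans-self chimera and is cut to the longer span.
Queries with no trans-self call are re-checked with spans merged across all
targets (trans-multi-gene). Only cut sequences longer than 200 bp are kept.
Cis chimeras are deliberately never cut — against distant model species,
tandem duplication and rate heterogeneity mimic them too easily.

**Redundancy reduction** (`pick-oases`, `pick-trinity`). Oases-style: per
locus, keep transcripts longer than a fraction (default 0.3) of the locus
maximum, then pick the transcript with the highest geometric-mean node read
coverage; combining single-k assemblies, loci at k = 21…51 contribute only
when they hold 1 transcript (`filter1`) or 1 or 3 (`filter1and3`), with k=61
unrestricted. Trinity-style: keep the highest-IsoPct isoform per
subcomponent (`pickH`) or drop the lowest from subcomponents with several
(`removeL`).

**Read cleaning** (`clean-reads`). Pairs are dropped when a mate's mean
quality is ≤ 32; 3' bases with quality < 10 are trimmed and pairs with a
mate ≤ 72 bp are dropped; pairs with adaptor contamination are dropped.

## Worked example

Generate a synthetic benchmark (20 genes, 60 derived transcripts, 12
injected chimeras — 3 per type), evaluate it against its own reference, and
run the reference-free trans-chimera cleaner:

```bash
transqc simulate --n-genes 20 --chimeras-per-type 3 --seed 11 --out demo/sim
transqc eval-ref --psl demo/sim/hits.psl --assembly demo/sim/assembly.fa \
                 --reference demo/sim/reference.fa --out-dir demo/eval
transqc clean-trans --assembly demo/sim/assembly.fa \
                    --blastx demo/sim/hits.blastx.tsv --out-dir demo/trans
```

`eval-ref` prints the coverage report:

```json
{"pct_ref_bp": 87.4032798244601, "pct_genes_gt200": 100.0,
 "pct_genes_ge80": 75.0, "redundancy": 3.6,
 "chimera_rate": 16.666666666666668,
 "n_queries_with_hits": 72, "n_refs_with_hits": 20}
```

i.e. all 20 genes are recovered to > 200 bp, 15/20 to ≥ 80% of their length,
87.4% of reference base pairs are assembled, there are on average 3.6
assembled sequences per recovered gene, and 12 of the 72 transcripts with
hits (16.7%) are chimeric — exactly the 12 injected ones.  `clean-trans`
reports `6 trans-chimera call(s); 72 sequences retained` and writes their
coordinates:

```
query_id             call_type   plus_span  minus_span  retained  target_id  kept
chim_trans_self_006  trans_self  0-479      479-922     0-479     ref17      True
chim_trans_self_007  trans_self  0-477      477-837     0-477     ref13      True
```

The 6 trans-type chimeras are cut to their longer component; the 6 cis-type
chimeras pass through untouched, as intended.

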