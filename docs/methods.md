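# Methods

This note documents the models and rules `transqc` implements, the design
choices that were genuinely open, what the synthetic generator does and does
not emulate, and known limitations.

## Chimera model

An assembled transcript is *chimeric* when its sequence derives from more
than one true transcript region.  Causes include de Bruijn graph
misassembly (the dominant one for short-read assemblies), PCR-mediated
recombination during library preparation, and genuine biology (gene fusion,
trans-splicing); the toolkit does not attempt to distinguish them.  Typing
is on two axes — component gene identity (self vs multi-gene) and joint
orientation (cis vs trans) — giving four classes.  Trans-self chimeras, a
hallmark of palindromic graph artifacts, are the class single-direction
pipelines miss entirely, which is why the taxonomy matters.

## Coordinate conventions

All internal coordinates are 0-based half-open.  PSL is natively so and is
passed through; tabular translated-search records (1-based inclusive, query
coordinates reversed for minus-frame HSPs) are normalized at parse time.
An HSP's reading direction is taken from the sign of a frame column when
the column spec has one, else from query-coordinate reversal — both
dialects occur in the wild and the column layout of translated-search
output is not standardized, so the column spec is configurable
(default: `qseqid sseqid pident length qstart qend sstart send evalue
bitscore sframe`).

PSL percent identity is always recomputed as
`matches / (matches + mismatches + repMatches) × 100` rather than trusted
from annotation: PSL has no identity column, and the 95% rule must be
deterministic.

## Thresholds

One `Thresholds` block is shared by every detector so each constant lives
in exactly one place.  Defaults: nucleotide hits need ≥ 95% identity and
≥ 100 matching bases; HSPs need ≥ 30% identity and ≥ 100 bp query coverage;
the minimal-overlap rule requires overlap < 60 bp AND < 20% of the shorter
coverage (a conjunction — both prints of the rule in circulation order the
clauses differently but state the same cutoffs); sequences must be > 200 bp
(strict) to be retained; a reference is organellar when hits at ≥ 95%
identity cover ≥ 80% of it, where "combined region" is the interval union,
not the span.  All inequalities are read literally: "≤ 32", "≤ 72 bp",
"lower than 95%", "less than 100" give inclusive rejection / inclusive-keep
boundaries as written, and the boundary behavior is pinned by tests.

## Reference-based classification: open choices

The published rule set is silent on several ties; determinism forced a
choice, and the choice is documented so the oracles agree:

* **Best hit** = most matching bases; ties break to the longer query
  coverage, then lexicographic target id.
* **Evidence partner** when several hits pass the minimal-overlap test
  against the best hit: the one with the most matches (strongest second
  signal).  Comparison is every non-best hit vs the best hit only, not all
  pairs.
* When no comparison flags a chimera, the **longest** hit becomes the best
  hit for coverage purposes.
* Per-reference coverage is the best hit's *target-interval length*, not
  its match count: reference coverage counts assembled reference bases,
  and the alignment extent is the direct measure.
* Chimeric queries contribute no coverage but do count in redundancy's
  numerator — they are assembled sequences with hits.
* The "percent of reference bp assembled" counts a gene's contribution
  only when that gene's own coverage exceeds 200 bp (the same cutoff as
  the gene-count metric); whether the original definition conditions on
  gene coverage or transcript length is ambiguous, and this reading keeps
  the two metrics consistent.

## Trans-chimera screening: open choices

* Query–target pairs are visited in descending best-bitscore order (ties:
  lexicographic target id).  "All subsequent HSPs are ignored" after a call
  makes order-dependence real; descending score mirrors search-output
  convention.
* Same-direction "merged" coverage is the min-start/max-end **span**, not
  the union: fragments of one ORF split by indels represent a single ORF.
* Trans-self evidence requires only the same target id, not the same
  target region.
* Cutting keeps exactly the retained span, with no extension toward the
  sequence ends; when the plus and minus spans tie in length the plus span
  is retained.
* Cis chimeras are never cut (by design, see README).

## Isoform selection: open choices

* The locus transcript count used by `filter1`/`filter1and3` is the **raw**
  count, before the relative-length filter — the count is a property of
  the locus, not of the filtered subset.
* The relative-length filter is strict (`length > frac × max`), with the
  longest transcript always surviving (relevant only at `frac = 1`).
* Geometric-mean coverage is unweighted across nodes, and a zero-coverage
  node drives it to 0 with no pseudo-count: isoforms threading regions of
  essentially no expression are exactly the artifacts the score penalizes.
* Tie-breaks everywhere: higher gm-coverage → longer → lexicographic id.
* Node coverages arrive via a neutral sidecar TSV
  (`locus_id, transcript_id, length, k, node_coverages`) rather than by
  parsing assembler-internal files, since assembler versions disagree on
  where node coverage lives.
* Downstream similarity merging is external to this package; the published
  workflow used cap3 (`-o 200 -p 99`) or CD-HIT-EST (`-c 0.98 -n 10 -r 1`)
  on the selected representatives.

## Read cleaning: open choices

* Rule order is fixed (mean-quality → trim+length → adaptor), and the
  rejection reason reported is the first rule that fires.
* Mean quality is the arithmetic mean of decoded Phred scores over the
  untrimmed read.
* Adaptor contamination is an exact substring match of a supplied adaptor
  anywhere in the (trimmed) read, or of its first 12 bases at the read's
  3' end; no alignment heuristics, so the rule is deterministic and
  testable.  An adaptor match rejects the whole pair, consistent with the
  pair-level rules 1–2.
* Phred+33 is the default encoding, Phred+64 selectable.

## The synthetic generator

`simgen` emulates every input the detectors consume: a random reference
gene set (uniform lengths, configurable GC), redundant derived transcripts
(substrings, optional point mutations), injected chimeras of all four types
built by concatenating reference segments (second segment
reverse-complemented for trans types) with recorded junctions, analytic
PSL/tabular hit tables computed exactly from provenance, locus and isoform
tables, and paired FASTQ constructed to pass or fail each cleaning rule.
Each operation draws from its own seeded `random.Random` stream, so output
is byte-identical across runs and adding chimeras never perturbs reference
generation.

Hits are emitted analytically rather than by running an aligner: with
known provenance the exact hit geometry is computable, the tests need no
external tools, and the detectors are exercised on precisely the geometry
the rules address.  The translated-search emulation treats each reference
as its own protein target with coordinates 1:1 in nucleotide space — the
detection rules consume only query-side nucleotide intervals, so
protein-space realism adds nothing to correctness.

What it does **not** emulate, and hence what passing tests do not show:
alignment noise (split/merged hits at junctions, spurious secondary hits),
paralogy and repeat families in the reference, realistic read error models
and insert-size distributions, strand ambiguity of real assemblies (clean
derived transcripts are all plus-strand), or protein-space effects of
frameshifts.  Performance numbers on this benchmark are upper bounds on
real-data behavior; the benchmark's purpose is exactness of the rules, not
realism of the noise.

Default benchmark conditions: 50 reference genes of 800–2500 bp, 3 derived
transcripts per gene (fragments 50–100% of gene length, floor 250 bp),
10 chimeras per type with components of 250–500 bp (distinct lengths, so
"the longer component" is unambiguous; all above the 100-bp detection
floors), mutation rate 0.  These sizes make every acceptance check exact
while the whole pipeline runs in about a second.  A component below 100 bp
can never pass the hit/HSP filters; the generator records such chimeras as
`detectable = false`.

## Known limitations

* The reference-based classifier compares non-best hits to the best hit
  only; a chimera whose best hit spans the junction region of both
  components can escape detection.  This mirrors the published rule.
* Trans-self detection merges all HSPs of a pair into two spans; nested
  arrangements (plus-minus-plus) are collapsed and the retained span can
  contain foreign sequence.
* Redundancy counts distinct query/target ids in the filtered hit set; it
  is not an expression-weighted measure.
* The read cleaner holds surviving records in memory before writing; it is
  sized for QC-scale fixtures, not production-scale lanes.
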