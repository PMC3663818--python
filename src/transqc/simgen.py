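"""Deterministic synthetic-data generator with machine-readable ground truth.

Builds every input the other modules consume — a reference gene set, derived
transcripts, injected chimeras of all four types with recorded breakpoints,
alignment hit tables, locus/isoform tables, and paired FASTQ — all computed
analytically from known provenance.  No aligner is run: because every
transcript's origin is known exactly, the hit/HSP tables are emitted with
exact coordinates, which exercises the detection rules on precisely the
geometry they address.

Determinism: every operation takes an integer seed and uses its own
``random.Random`` stream, so identical parameters give byte-identical output
and adding chimeras never perturbs reference generation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from transqc.seqformats import (
    ConfigError,
    Hit,
    Interval,
    revcomp,
    write_fasta,
    write_psl,
)
from transqc.isopick import IsoformRecord, LocusTranscript

BASES = "ACGT"
CHIMERA_TYPES = ("cis_self", "cis_multi", "trans_self", "trans_multi")

# a component shorter than this cannot pass the 100-matching-base /
# 100-bp-query-coverage filters, so such chimeras are marked undetectable
MIN_DETECTABLE_COMPONENT = 100

DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass(frozen=True)
class TruthSegment:
    ref_id: str
    ref_interval: Interval
    strand: str  # "+" or "-"
    mutations: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one synthetic transcript."""

    transcript_id: str
    origin: tuple[TruthSegment, ...]
    chimera_type: str  # "none" or one of CHIMERA_TYPES
    junctions: tuple[int, ...] = ()
    detectable: bool = True

    @property
    def length(self) -> int:
        return sum(len(s.ref_interval) for s in self.origin)

    def query_intervals(self) -> list[Interval]:
        """Transcript-coordinate interval of each origin segment."""
        out, pos = [], 0
        for seg in self.origin:
            out.append(Interval(pos, pos + len(seg.ref_interval)))
            pos += len(seg.ref_interval)
        return out


# ---------------------------------------------------------------------------
# reference and transcript simulation


def _random_seq(rng: random.Random, length: int, gc: float) -> str:
    gc_half, at_half = gc / 2, (1 - gc) / 2
    return "".join(
        rng.choices("GCAT", weights=(gc_half, gc_half, at_half, at_half), k=length)
    )


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (500, 2000),
    gc: float = 0.45,
    seed: int = 0,
) -> dict[str, str]:
    """Generate a reference gene set: random sequences, uniform lengths."""
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ConfigError(f"degenerate length range {length_range}")
    rng = random.Random(seed)
    refs: dict[str, str] = {}
    width = len(str(n_genes))
    for i in range(n_genes):
        length = rng.randint(lo, hi)
        refs[f"ref{i:0{width}d}"] = _random_seq(rng, length, gc)
    return refs


def _mutate(rng: random.Random, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    chars = list(seq)
    n_mut = 0
    for i, base in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in BASES if b != base])
            n_mut += 1
    return "".join(chars), n_mut


def simulate_transcripts(
    refs: Mapping[str, str],
    n_per_gene: int = 3,
    fragment_frac_range: tuple[float, float] = (0.5, 1.0),
    mutation_rate: float = 0.0,
    seed: int = 0,
    min_fragment: int = 250,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Derive redundant transcripts as (possibly mutated) reference substrings.

    Emulates assembly redundancy: several partially overlapping fragments
    per gene.  Fragment lengths are uniform in ``fragment_frac_range`` of
    the gene length, floored at ``min_fragment`` so every clean transcript
    clears the downstream hit filters.
    """
    if not 0 <= mutation_rate < 1:
        raise ConfigError("mutation_rate must be in [0, 1)")
    rng = random.Random(seed)
    transcripts: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for ref_id in sorted(refs):
        seq = refs[ref_id]
        for j in range(n_per_gene):
            frac = rng.uniform(*fragment_frac_range)
            frag_len = max(min(int(round(frac * len(seq))), len(seq)), min(min_fragment, len(seq)))
            start = rng.randint(0, len(seq) - frag_len)
            fragment = seq[start : start + frag_len]
            mutated, n_mut = _mutate(rng, fragment, mutation_rate)
            tid = f"t_{ref_id}_{j}"
            transcripts[tid] = mutated
            truth.append(
                TruthRecord(
                    transcript_id=tid,
                    origin=(
                        TruthSegment(ref_id, Interval(start, start + frag_len), "+", n_mut),
                    ),
                    chimera_type="none",
                )
            )
    return transcripts, truth


# ---------------------------------------------------------------------------
# chimera injection


def inject_chimeras(
    refs: Mapping[str, str],
    counts_per_type: Mapping[str, int],
    seed: int = 0,
    component_len_range: tuple[int, int] = (250, 500),
    intra_ref_gap: int = 50,
    mutation_rate: float = 0.0,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Construct chimeric transcripts of the four types with known junctions.

    Each chimera joins two components drawn from the reference set: for
    *self* types both from one gene (disjoint regions), for *multi* types
    from two genes; *trans* types reverse-complement the second component.
    Components are sized within ``component_len_range`` — above the
    detection thresholds by default — and the junction position is recorded.
    """
    unknown = set(counts_per_type) - set(CHIMERA_TYPES)
    if unknown:
        raise ConfigError(f"unknown chimera type(s): {sorted(unknown)}")
    lo, hi = component_len_range
    if lo <= 0 or hi < lo:
        raise ConfigError(f"degenerate component length range {component_len_range}")
    rng = random.Random(seed)
    ref_ids = sorted(refs)
    long_refs = [r for r in ref_ids if len(refs[r]) >= 2 * hi + intra_ref_gap]
    need_self = counts_per_type.get("cis_self", 0) + counts_per_type.get("trans_self", 0)
    if need_self and not long_refs:
        raise ConfigError(
            "no reference long enough for self-chimera construction "
            f"(need >= {2 * hi + intra_ref_gap} bp)"
        )
    eligible = [r for r in ref_ids if len(refs[r]) >= hi]
    if len(eligible) < 2 and (
        counts_per_type.get("cis_multi", 0) or counts_per_type.get("trans_multi", 0)
    ):
        raise ConfigError("need at least two references of sufficient length")

    transcripts: dict[str, str] = {}
    truth: list[TruthRecord] = []
    counter = 0
    for ctype in CHIMERA_TYPES:
        for _ in range(counts_per_type.get(ctype, 0)):
            len1, len2 = rng.randint(lo, hi), rng.randint(lo, hi)
            while len1 == len2:  # distinct lengths keep "longer component" unambiguous
                len2 = rng.randint(lo, hi)
            if ctype.endswith("_self"):
                ref_a = ref_b = rng.choice(long_refs)
                seq = refs[ref_a]
                start1 = rng.randint(0, len(seq) - len1 - len2 - intra_ref_gap)
                start2 = rng.randint(start1 + len1 + intra_ref_gap, len(seq) - len2)
            else:
                ref_a, ref_b = rng.sample(eligible, 2)
                start1 = rng.randint(0, len(refs[ref_a]) - len1)
                start2 = rng.randint(0, len(refs[ref_b]) - len2)
            part1 = refs[ref_a][start1 : start1 + len1]
            part2 = refs[ref_b][start2 : start2 + len2]
            strand2 = "-" if ctype.startswith("trans") else "+"
            if strand2 == "-":
                part2 = revcomp(part2)
            part1, mut1 = _mutate(rng, part1, mutation_rate)
            part2, mut2 = _mutate(rng, part2, mutation_rate)
            tid = f"chim_{ctype}_{counter:03d}"
            counter += 1
            transcripts[tid] = part1 + part2
            truth.append(
                TruthRecord(
                    transcript_id=tid,
                    origin=(
                        TruthSegment(ref_a, Interval(start1, start1 + len1), "+", mut1),
                        TruthSegment(ref_b, Interval(start2, start2 + len2), strand2, mut2),
                    ),
                    chimera_type=ctype,
                    junctions=(len1,),
                    detectable=min(len1, len2) >= MIN_DETECTABLE_COMPONENT,
                )
            )
    return transcripts, truth


# ---------------------------------------------------------------------------
# analytic hit emission


def truth_to_hits(truth: Sequence[TruthRecord], refs: Mapping[str, str]) -> list[Hit]:
    """One nucleotide hit per origin segment, with exact coordinates."""
    hits: list[Hit] = []
    for rec in truth:
        q_ivs = rec.query_intervals()
        for seg, q_iv in zip(rec.origin, q_ivs):
            seg_len = len(seg.ref_interval)
            hits.append(
                Hit(
                    query_id=rec.transcript_id,
                    target_id=seg.ref_id,
                    strand=seg.strand,
                    q_interval=q_iv,
                    t_interval=seg.ref_interval,
                    matches=seg_len - seg.mutations,
                    mismatches=seg.mutations,
                    query_length=rec.length,
                    target_length=len(refs[seg.ref_id]),
                )
            )
    return hits


def emit_hits(
    truth: Sequence[TruthRecord],
    refs: Mapping[str, str],
    style: str,
    path,
) -> None:
    """Write the analytic hit table in PSL or tabular-translated-search form.

    PSL rows are 0-based half-open.  Tabular rows are 1-based inclusive
    with reversed query coordinates and a negative frame for minus-direction
    segments (the translated-search emulation treats each reference as its
    own protein target, coordinates 1:1 in nucleotide space — the detection
    rules only consume query-side nucleotide intervals).
    """
    if style == "psl":
        write_psl(truth_to_hits(truth, refs), path)
        return
    if style != "blast_tab":
        raise ConfigError(f"style must be 'psl' or 'blast_tab', got {style!r}")
    with open(path, "w") as fh:
        for rec in truth:
            for seg, q_iv in zip(rec.origin, rec.query_intervals()):
                seg_len = len(seg.ref_interval)
                matches = seg_len - seg.mutations
                pident = 100.0 * matches / seg_len
                if seg.strand == "+":
                    qstart, qend, frame = q_iv.start + 1, q_iv.end, 1
                else:
                    qstart, qend, frame = q_iv.end, q_iv.start + 1, -1
                row = [
                    rec.transcript_id,
                    seg.ref_id,
                    f"{pident:.2f}",
                    seg_len,
                    qstart,
                    qend,
                    seg.ref_interval.start + 1,
                    seg.ref_interval.end,
                    "1e-30",
                    f"{2.0 * matches:.1f}",
                    frame,
                ]
                fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# FASTQ emission for the read-cleaning rules


def emit_fastq(
    pairs_spec: Mapping[str, int],
    out1,
    out2,
    seed: int = 0,
    read_len: int = 90,
    adaptor: str = DEFAULT_ADAPTOR,
) -> dict[str, int]:
    """Write a synchronized FASTQ pair built to pass/fail each cleaning rule.

    ``pairs_spec`` maps {'pass', 'low_mean', 'short_after_trim', 'adaptor'}
    to pair counts.  Construction per category:

    * pass — quality 40 throughout;
    * low_mean — mate 1 at uniform quality 20 (mean <= 32);
    * short_after_trim — last ``read_len - 70`` bases of mate 1 at quality 5
      (trims to 70 <= 72 bp) with the remainder at 40, which keeps the mean
      above 32 so the pair reaches rule 2;
    * adaptor — quality 40, the adaptor embedded mid-read in mate 2.
    """
    known = {"pass", "low_mean", "short_after_trim", "adaptor"}
    unknown = set(pairs_spec) - known
    if unknown:
        raise ConfigError(f"unknown pair category: {sorted(unknown)}")
    if read_len < 80:
        raise ConfigError("read_len must be >= 80 for the trim construction")
    rng = random.Random(seed)

    def clean_read() -> str:
        while True:
            seq = _random_seq(rng, read_len, 0.5)
            if adaptor not in seq and adaptor[:12] not in seq:
                return seq

    lines1: list[str] = []
    lines2: list[str] = []
    counts = {k: 0 for k in known}
    idx = 0
    for category in ("pass", "low_mean", "short_after_trim", "adaptor"):
        for _ in range(pairs_spec.get(category, 0)):
            name = f"pair{idx:05d}"
            idx += 1
            counts[category] += 1
            seq1, seq2 = clean_read(), clean_read()
            q_hi = chr(40 + 33) * read_len
            if category == "pass":
                q1, q2 = q_hi, q_hi
            elif category == "low_mean":
                q1, q2 = chr(20 + 33) * read_len, q_hi
            elif category == "short_after_trim":
                n_low = read_len - 70
                q1 = chr(40 + 33) * (read_len - n_low) + chr(5 + 33) * n_low
                q2 = q_hi
            else:  # adaptor
                pos = 30
                seq2 = seq2[:pos] + adaptor + seq2[pos + len(adaptor) :]
                q1, q2 = q_hi, q_hi
            lines1 += [f"@{name}/1", seq1, "+", q1]
            lines2 += [f"@{name}/2", seq2, "+", q2]
    Path(out1).write_text("\n".join(lines1) + ("\n" if lines1 else ""))
    Path(out2).write_text("\n".join(lines2) + ("\n" if lines2 else ""))
    return counts


# ---------------------------------------------------------------------------
# locus / isoform tables for the selection strategies


def generate_locus_tables(
    ks: Sequence[int] = (21, 31, 41, 51, 61),
    n_loci: int = 30,
    max_transcripts: int = 5,
    seed: int = 0,
) -> dict[int, list[LocusTranscript]]:
    """Multi-k locus tables with 1..max_transcripts isoforms per locus."""
    out: dict[int, list[LocusTranscript]] = {}
    for k in ks:
        rng = random.Random(seed * 1000 + k)  # per-k stream
        rows: list[LocusTranscript] = []
        for li in range(n_loci):
            n_tr = rng.randint(1, max_transcripts)
            for ti in range(n_tr):
                n_nodes = rng.randint(1, 6)
                covs = tuple(round(rng.uniform(0.5, 200.0), 3) for _ in range(n_nodes))
                rows.append(
                    LocusTranscript(
                        locus_id=f"k{k}_locus{li:03d}",
                        transcript_id=f"k{k}_locus{li:03d}_t{ti}",
                        length=rng.randint(150, 2500),
                        node_coverages=covs,
                        k=k,
                    )
                )
        out[k] = rows
    return out


def generate_isoform_table(
    n_subcomponents: int = 40,
    max_isoforms: int = 4,
    seed: int = 0,
) -> list[IsoformRecord]:
    """Trinity/RSEM-style isoform-percentage records."""
    rng = random.Random(seed)
    rows: list[IsoformRecord] = []
    for ci in range(n_subcomponents):
        n_iso = rng.randint(1, max_isoforms)
        raw = [rng.uniform(1, 100) for _ in range(n_iso)]
        total = sum(raw)
        for ii, w in enumerate(raw):
            rows.append(
                IsoformRecord(
                    component_id=f"comp{ci:03d}",
                    subcomponent_id=f"comp{ci:03d}_seq0",
                    isoform_id=f"comp{ci:03d}_seq0_iso{ii}",
                    iso_pct=round(100.0 * w / total, 2),
                    length=rng.randint(200, 3000),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# full benchmark scenario


@dataclass
class Scenario:
    """A complete synthetic benchmark: references, transcripts, ground truth."""

    refs: dict[str, str]
    transcripts: dict[str, str]
    truth: list[TruthRecord] = field(default_factory=list)

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.refs.items()}

    @property
    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.transcript_id: t for t in self.truth}


def build_scenario(
    n_genes: int = 50,
    n_per_gene: int = 3,
    chimeras_per_type: int = 10,
    mutation_rate: float = 0.0,
    seed: int = 42,
    length_range: tuple[int, int] = (800, 2500),
) -> Scenario:
    """The standard benchmark: clean derived transcripts plus injected
    chimeras of all four types, all components above detection thresholds."""
    refs = generate_reference(n_genes, length_range=length_range, seed=seed)
    transcripts, truth = simulate_transcripts(
        refs, n_per_gene=n_per_gene, mutation_rate=mutation_rate, seed=seed + 1
    )
    chim, chim_truth = inject_chimeras(
        refs,
        {t: chimeras_per_type for t in CHIMERA_TYPES},
        seed=seed + 2,
        mutation_rate=mutation_rate,
    )
    transcripts.update(chim)
    truth.extend(chim_truth)
    return Scenario(refs=refs, transcripts=transcripts, truth=truth)


# ---------------------------------------------------------------------------
# on-disk fixture directories

TRUTH_COLUMNS = ["transcript_id", "chimera_type", "detectable", "junctions", "segments"]


def write_truth_tsv(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for rec in truth:
            segments = ";".join(
                f"{s.ref_id}:{s.ref_interval.start}-{s.ref_interval.end}:{s.strand}"
                for s in rec.origin
            )
            junctions = ",".join(str(j) for j in rec.junctions)
            fh.write(
                f"{rec.transcript_id}\t{rec.chimera_type}\t"
                f"{int(rec.detectable)}\t{junctions}\t{segments}\n"
            )


def write_scenario(scenario: Scenario, outdir, params: dict | None = None) -> dict:
    """Write a scenario directory: FASTAs, PSL, tabular hits, truth, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.refs, outdir / "reference.fa")
    write_fasta(scenario.transcripts, outdir / "assembly.fa")
    emit_hits(scenario.truth, scenario.refs, "psl", outdir / "hits.psl")
    emit_hits(scenario.truth, scenario.refs, "blast_tab", outdir / "hits.blastx.tsv")
    write_truth_tsv(scenario.truth, outdir / "truth.tsv")
    manifest = {
        "n_refs": len(scenario.refs),
        "n_transcripts": len(scenario.transcripts),
        "n_chimeras": sum(1 for t in scenario.truth if t.chimera_type != "none"),
        "params": params or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
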