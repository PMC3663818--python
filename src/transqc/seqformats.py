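"""Alignment-format readers/writers and the interval arithmetic shared by
every detector.

All internal query/target coordinates are 0-based half-open, regardless of
the source dialect: PSL is native, tabular translated-search output (1-based
inclusive, with reversed query coordinates for minus-frame records) is
converted at parse time.  One convention everywhere eliminates the usual
off-by-one bugs between the chimera detectors.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an alignment/sequence file."""


class ConfigError(ValueError):
    """An invalid configuration value (column spec, threshold, path set)."""


class DataError(ValueError):
    """Inconsistent data (id mismatches, length mismatches, missing keys)."""


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval ``[start, end)`` with positive length."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def interval_overlap(a: Interval, b: Interval) -> int:
    """Length of the intersection of two intervals; 0 when disjoint."""
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_length(intervals: Iterable[Interval]) -> int:
    """Total number of positions covered by the union of the intervals.

    The "combined region" of a set of alignments: overlapping bases are
    counted once, gaps between intervals are not counted (union, not span).
    """
    ivs = sorted(intervals, key=lambda iv: iv.start)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for iv in ivs:
        if cur_start is None or iv.start > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def span(intervals: Sequence[Interval]) -> Interval:
    """Minimal single interval containing every input interval."""
    if not intervals:
        raise ValueError("span() of an empty interval set")
    return Interval(min(iv.start for iv in intervals), max(iv.end for iv in intervals))


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class Thresholds:
    """Every tunable cutoff used by the detectors, with the standard defaults.

    min_blat_identity : %, nucleotide hits below this similarity are ignored
    min_blat_matches : bp, hits with fewer matching bases are ignored
    max_overlap_bp / max_overlap_frac : the minimal-overlap rule — two query
        coverages are "separate" when their overlap is below BOTH 60 bp and
        20% of the shorter of the pair
    min_transcript_len : bp, sequences at or below this are dropped
    min_hsp_identity : %, translated-search HSPs below this are ignored
    min_hsp_qcov : bp, HSPs with shorter query coverage are ignored
    organellar_cov_frac / organellar_identity : a reference transcript is
        treated as organellar when hits at >= this identity cover >= this
        fraction of its length
    """

    min_blat_identity: float = 95.0
    min_blat_matches: int = 100
    max_overlap_bp: int = 60
    max_overlap_frac: float = 0.20
    min_transcript_len: int = 200
    min_hsp_identity: float = 30.0
    min_hsp_qcov: int = 100
    organellar_cov_frac: float = 0.80
    organellar_identity: float = 95.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown threshold name(s): {sorted(unknown)}")
        return cls(**mapping)

    def replace(self, **overrides) -> "Thresholds":
        return replace(self, **overrides)


def is_minimal_overlap(a: Interval, b: Interval, t: Thresholds) -> bool:
    """True when two query coverages have no, or minimal, overlap.

    Both clauses are required: the overlap must be below ``max_overlap_bp``
    AND below ``max_overlap_frac`` of the shorter interval.  This is the
    single rule shared by the reference-based chimera test and the
    translated-search trans-chimera test.
    """
    ov = interval_overlap(a, b)
    return ov < t.max_overlap_bp and ov < t.max_overlap_frac * min(len(a), len(b))


# ---------------------------------------------------------------------------
# alignment records


@dataclass(frozen=True)
class Hit:
    """One nucleotide alignment of an assembled transcript to a reference.

    ``matches``/``mismatches``/``rep_matches`` follow PSL semantics; percent
    identity is always recomputed from those counts (PSL carries no identity
    column) so that the "95% similarity" rule is deterministic.
    """

    query_id: str
    target_id: str
    strand: str  # "+" or "-"
    q_interval: Interval
    t_interval: Interval
    matches: int
    query_length: int
    target_length: int
    mismatches: int = 0
    rep_matches: int = 0
    percent_identity: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.matches < 0:
            raise ValueError("matches must be >= 0")
        if self.percent_identity < 0:
            denom = self.matches + self.mismatches + self.rep_matches
            pid = 100.0 * self.matches / denom if denom else 0.0
            object.__setattr__(self, "percent_identity", pid)


@dataclass(frozen=True)
class HSPRecord:
    """One high-scoring segment pair from a translated (blastx-style) search.

    ``direction`` is the sign of the translated reading frame ("plus" or
    "minus"); ``q_interval`` is always stored in ascending nucleotide
    coordinates even when the source file lists them reversed.
    """

    query_id: str
    target_id: str
    q_interval: Interval
    direction: str  # "plus" or "minus"
    percent_identity: float
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.direction not in ("plus", "minus"):
            raise ValueError(f"direction must be 'plus'/'minus', got {self.direction!r}")


# ---------------------------------------------------------------------------
# PSL (21-column BLAT output)

PSL_COLUMNS = 21


def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_psl(path) -> list[Hit]:
    """Parse a 21-column PSL file (header optional) into :class:`Hit` records.

    PSL coordinates are already 0-based half-open and are preserved.  The
    strand field's first character gives the query strand (translated BLAT
    writes two characters).
    """
    hits: list[Hit] = []
    header_until = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if lineno == 1 and line.startswith("psLayout"):
                header_until = 5  # fixed 5-line header: banner, blank, 2 column rows, rule
            if lineno <= header_until or not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != PSL_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {PSL_COLUMNS} PSL columns, got {len(cols)}"
                )
            try:
                matches = int(cols[0])
                mismatches = int(cols[1])
                rep_matches = int(cols[2])
                strand = cols[8][0]
                q_name = cols[9]
                q_size = int(cols[10])
                q_start, q_end = int(cols[11]), int(cols[12])
                t_name = cols[13]
                t_size = int(cols[14])
                t_start, t_end = int(cols[15]), int(cols[16])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if min(q_start, q_end, t_start, t_end) < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            hits.append(
                Hit(
                    query_id=q_name,
                    target_id=t_name,
                    strand=strand,
                    q_interval=Interval(q_start, q_end),
                    t_interval=Interval(t_start, t_end),
                    matches=matches,
                    mismatches=mismatches,
                    rep_matches=rep_matches,
                    query_length=q_size,
                    target_length=t_size,
                )
            )
    return hits



def write_psl(hits: Iterable[Hit], path, header: bool = False) -> None:
    """Write hits as 21-column PSL (single-block alignments)."""
    with open(path, "w") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write("match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ\tQ   \tQ    \tQ  \tT\tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n")
            fh.write("     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname\tsize\tstart\tend\tname\tsize\tstart\tend\tcount\n")
            fh.write("-" * 120 + "\n")
        for h in hits:
            block = len(h.q_interval)
            row = [
                h.matches, h.mismatches, h.rep_matches, 0, 0, 0, 0, 0,
                h.strand,
                h.query_id, h.query_length, h.q_interval.start, h.q_interval.end,
                h.target_id, h.target_length, h.t_interval.start, h.t_interval.end,
                1, f"{block},", f"{h.q_interval.start},", f"{h.t_interval.start},",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# tabular translated-search output (blast outfmt-6 style)

DEFAULT_BLAST_COLUMNS = (
    "qseqid sseqid pident length qstart qend sstart send evalue bitscore sframe"
)

_REQUIRED_BLAST_FIELDS = {"qseqid", "sseqid", "pident", "qstart", "qend", "evalue", "bitscore"}


def parse_blast_tab(path, columns: str = DEFAULT_BLAST_COLUMNS) -> list[HSPRecord]:
    """Parse tab-separated translated-search records into HSPs.

    ``columns`` names the fields in file order (blast ``-outfmt 6`` style).
    Direction is taken from the sign of ``sframe``/``qframe`` when such a
    column exists, otherwise from query-coordinate reversal.  Query
    coordinates (1-based inclusive, possibly reversed) are normalized to
    ascending 0-based half-open.
    """
    names = columns.split()
    missing = _REQUIRED_BLAST_FIELDS - set(names)
    if missing:
        raise ConfigError(f"column spec missing required field(s): {sorted(missing)}")
    frame_col = next((n for n in ("sframe", "qframe", "frames") if n in names), None)
    idx = {n: i for i, n in enumerate(names)}

    records: list[HSPRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected >= {len(names)} columns, got {len(cols)}"
                )
            try:
                qstart = int(cols[idx["qstart"]])
                qend = int(cols[idx["qend"]])
                pident = float(cols[idx["pident"]])
                evalue = float(cols[idx["evalue"]])
                bitscore = float(cols[idx["bitscore"]])
                frame = None
                if frame_col is not None:
                    frame = int(cols[idx[frame_col]].split("/")[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if frame is not None:
                direction = "minus" if frame < 0 else "plus"
            else:
                direction = "minus" if qstart > qend else "plus"
            lo, hi = min(qstart, qend), max(qstart, qend)
            records.append(
                HSPRecord(
                    query_id=cols[idx["qseqid"]],
                    target_id=cols[idx["sseqid"]],
                    q_interval=Interval(lo - 1, hi),
                    direction=direction,
                    percent_identity=pident,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return records


# ---------------------------------------------------------------------------
# FASTA / FASTQ

FASTA_WRAP = 80


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    """Write sequences as FASTA wrapped at 80 columns."""
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def fasta_lengths(path) -> dict[str, int]:
    return {name: len(seq) for name, seq in read_fasta(path).items()}


def iter_fastq(path, encoding: str = "phred33") -> Iterator[SeqRecord]:
    """Iterate FASTQ records with qualities decoded to Phred integers."""
    fmt = {"phred33": "fastq", "phred64": "fastq-illumina"}.get(encoding)
    if fmt is None:
        raise ConfigError(f"unknown FASTQ encoding {encoding!r}")
    with _open_text(path) as fh:
        yield from SeqIO.parse(fh, fmt)


def write_fastq(records: Iterable[SeqRecord], path, encoding: str = "phred33") -> int:
    fmt = {"phred33": "fastq", "phred64": "fastq-illumina"}.get(encoding)
    if fmt is None:
        raise ConfigError(f"unknown FASTQ encoding {encoding!r}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        return SeqIO.write(records, fh, fmt)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
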