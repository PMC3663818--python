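"""Paired-end read cleaning.

Three rules, applied in order to each read pair:

1. drop the pair if either mate's mean Phred quality is <= ``min_mean_quality``
   (the mean is taken over the untrimmed read);
2. trim 3' bases with quality below ``trim_quality`` from each mate, then drop
   the pair if either trimmed mate is <= ``min_length`` bp;
3. drop the pair if either (trimmed) mate shows adaptor contamination.

Trimming only ever removes a 3' suffix: every surviving read is a prefix of
the input read.  Adaptor contamination is an exact substring match of a
supplied adaptor anywhere in the read, or of its first 12 bases at the read's
3' end — deterministic by construction, with no alignment heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from transqc.seqformats import DataError, iter_fastq, read_fasta, write_fastq

MIN_MEAN_QUALITY = 32.0  # pairs with a mate mean quality <= this are dropped
TRIM_QUALITY = 10  # 3' bases below this are trimmed
MIN_LENGTH = 72  # post-trim mates <= this are dropped
ADAPTOR_SEED_LEN = 12  # 3'-end match length for partial adaptors

REASONS = ("low_mean_quality", "short_after_trim", "adaptor")


@dataclass
class ReadPair:
    """One mate pair with decoded per-base Phred scores."""

    id: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise DataError(f"pair {self.id}: sequence/quality length mismatch")


@dataclass
class CleanSummary:
    total: int = 0
    surviving: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )


def _trim_3prime(seq: str, qual: Sequence[int], trim_quality: int) -> tuple[str, Sequence[int]]:
    end = len(seq)
    while end > 0 and qual[end - 1] < trim_quality:
        end -= 1
    return seq[:end], qual[:end]


def _has_adaptor(seq: str, adaptors: Sequence[str]) -> bool:
    for ad in adaptors:
        if ad and ad in seq:
            return True
        seed = ad[:ADAPTOR_SEED_LEN]
        if seed and len(seed) == ADAPTOR_SEED_LEN and seq.endswith(seed):
            return True
    return False


def clean_pair(
    pair: ReadPair,
    adaptors: Sequence[str] = (),
    *,
    min_mean_quality: float = MIN_MEAN_QUALITY,
    trim_quality: int = TRIM_QUALITY,
    min_length: int = MIN_LENGTH,
) -> tuple[ReadPair | None, str | None]:
    """Apply the three cleaning rules to one pair.

    Returns ``(cleaned_pair, None)`` for survivors, ``(None, reason)`` for
    rejections, with ``reason`` one of :data:`REASONS`.
    """
    # rule 1: mean quality, computed before any trimming
    for qual in (pair.qual1, pair.qual2):
        if not qual or sum(qual) / len(qual) <= min_mean_quality:
            return None, "low_mean_quality"
    # rule 2: 3' quality trim, then pair-level length filter
    seq1, qual1 = _trim_3prime(pair.seq1, pair.qual1, trim_quality)
    seq2, qual2 = _trim_3prime(pair.seq2, pair.qual2, trim_quality)
    if len(seq1) <= min_length or len(seq2) <= min_length:
        return None, "short_after_trim"
    # rule 3: adaptor contamination on the trimmed reads
    if _has_adaptor(seq1, adaptors) or _has_adaptor(seq2, adaptors):
        return None, "adaptor"
    return ReadPair(pair.id, seq1, seq2, qual1, qual2), None


def _pair_key(name: str) -> str:
    for suffix in ("/1", "/2"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _to_record(name: str, seq: str, qual: Sequence[int]) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = list(qual)
    return rec


def clean_fastq(
    in1,
    in2,
    out1,
    out2,
    adaptors: Sequence[str] = (),
    encoding: str = "phred33",
    *,
    min_mean_quality: float = MIN_MEAN_QUALITY,
    trim_quality: int = TRIM_QUALITY,
    min_length: int = MIN_LENGTH,
) -> CleanSummary:
    """Clean a synchronized FASTQ pair of files; write surviving pairs.

    Mates are matched positionally and their ids cross-checked (a ``/1`` or
    ``/2`` suffix is ignored); a mismatch raises :class:`DataError` at the
    first offending record.  Input order is preserved in the output.
    """
    summary = CleanSummary()
    survivors1: list[SeqRecord] = []
    survivors2: list[SeqRecord] = []
    it1, it2 = iter_fastq(in1, encoding), iter_fastq(in2, encoding)
    for rec1, rec2 in zip(it1, it2, strict=True):
        if _pair_key(rec1.id) != _pair_key(rec2.id):
            raise DataError(
                f"desynchronized mates at record {summary.total + 1}: "
                f"{rec1.id!r} vs {rec2.id!r}"
            )
        summary.total += 1
        pair = ReadPair(
            _pair_key(rec1.id),
            str(rec1.seq),
            str(rec2.seq),
            rec1.letter_annotations["phred_quality"],
            rec2.letter_annotations["phred_quality"],
        )
        cleaned, reason = clean_pair(
            pair,
            adaptors,
            min_mean_quality=min_mean_quality,
            trim_quality=trim_quality,
            min_length=min_length,
        )
        if cleaned is None:
            summary.rejected[reason] += 1
        else:
            summary.surviving += 1
            survivors1.append(_to_record(rec1.id, cleaned.seq1, cleaned.qual1))
            survivors2.append(_to_record(rec2.id, cleaned.seq2, cleaned.qual2))
    write_fastq(survivors1, out1, encoding)
    write_fastq(survivors2, out2, encoding)
    return summary


def load_adaptors(path) -> list[str]:
    """Read adaptor sequences from a FASTA file."""
    return list(read_fasta(path).values())
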