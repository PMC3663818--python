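"""Redundancy-reducing representative-isoform selection.

De Bruijn graph assemblers emit many isoforms per locus (Oases) or
component/subcomponent (Trinity): splice variants, paralogs, fragments, and
chimeras.  Phylogenomics wants one representative per gene.  Two families of
strategies are implemented:

* **Oases-style multi-k**: within each locus, drop transcripts shorter than a
  fraction of the locus maximum ("very short high-coverage motifs"), then
  keep the transcript with the highest geometric-mean node read coverage.
  The geometric mean penalizes isoforms containing low-expression nodes,
  which tend to be assembly artifacts.  Combining single-k assemblies, loci
  at the lower k values contribute a representative only when they hold one
  transcript (``filter1``) or one or three transcripts (``filter1and3``);
  the highest k is unrestricted so gene families and splice-variant-rich
  genes stay represented.
* **Trinity-style single-k**: using per-isoform expression percentages
  (IsoPct, from an RSEM-style table), either keep only the top isoform per
  subcomponent (``pickH``) or drop the bottom isoform from subcomponents
  with several (``removeL``).

Downstream similarity merging (cap3 ``-o 200 -p 99`` or CD-HIT-EST
``-c 0.98 -n 10 -r 1`` in the published workflow) is external to this
package; the selection output here is its input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from transqc.seqformats import ConfigError, DataError


@dataclass(frozen=True)
class LocusTranscript:
    """One assembled transcript with its locus and per-node read coverages."""

    locus_id: str
    transcript_id: str
    length: int
    node_coverages: tuple[float, ...]
    k: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not self.node_coverages:
            raise ValueError("node_coverages must be non-empty")


@dataclass(frozen=True)
class IsoformRecord:
    """One Trinity isoform with its estimated expression share."""

    component_id: str
    subcomponent_id: str
    isoform_id: str
    iso_pct: float
    length: int


def relative_length_filter(
    locus: Sequence[LocusTranscript], frac: float
) -> list[LocusTranscript]:
    """Keep transcripts longer than ``frac`` of the locus maximum length.

    The comparison is strict, so the longest transcript always survives.
    """
    if not locus:
        raise ValueError("relative_length_filter requires a non-empty locus")
    if not 0 < frac <= 1:
        raise ConfigError(f"frac must be in (0, 1], got {frac}")
    max_len = max(t.length for t in locus)
    return [t for t in locus if t.length > frac * max_len or t.length == max_len]


def geometric_mean_coverage(node_coverages: Sequence[float]) -> float:
    """Geometric mean of per-node read coverages, unweighted.

    A single zero-coverage node drives the result to 0 (no pseudo-count):
    isoforms threading regions of essentially no expression are exactly the
    likely misassemblies this score exists to penalize.
    """
    if not node_coverages:
        raise ValueError("node_coverages must be non-empty")
    if any(c < 0 for c in node_coverages):
        raise DataError("negative node coverage")
    if any(c == 0 for c in node_coverages):
        return 0.0
    return math.exp(sum(math.log(c) for c in node_coverages) / len(node_coverages))


def pick_representative(
    locus: Sequence[LocusTranscript], frac: float
) -> LocusTranscript:
    """The locus representative: length-filter, then highest gm-coverage.

    Ties break toward the longer transcript, then the lexicographically
    smaller id, so the choice is order-independent.
    """
    survivors = relative_length_filter(locus, frac)
    return min(
        survivors,
        key=lambda t: (-geometric_mean_coverage(t.node_coverages), -t.length, t.transcript_id),
    )


_ALLOWED_COUNTS = {"filter1": {1}, "filter1and3": {1, 3}}


def multi_k_filter(
    assemblies: Mapping[int, Sequence[LocusTranscript]],
    mode: str = "filter1",
    frac: float = 0.3,
    unrestricted_k: int = 61,
) -> list[LocusTranscript]:
    """Pool per-locus representatives across single-k assemblies.

    For every k except ``unrestricted_k``, a locus contributes its
    representative only when its raw transcript count (before the relative
    length filter) is in the allowed set — {1} for ``filter1``, {1, 3} for
    ``filter1and3``.  At ``unrestricted_k`` every locus contributes.
    """
    if mode not in _ALLOWED_COUNTS:
        raise ConfigError(f"mode must be one of {sorted(_ALLOWED_COUNTS)}, got {mode!r}")
    if unrestricted_k not in assemblies:
        raise ConfigError(f"unrestricted k={unrestricted_k} absent from assemblies")
    allowed = _ALLOWED_COUNTS[mode]
    selected: list[LocusTranscript] = []
    for k in sorted(assemblies):
        loci: dict[str, list[LocusTranscript]] = {}
        for t in assemblies[k]:
            loci.setdefault(t.locus_id, []).append(t)
        for locus_id in sorted(loci):
            members = loci[locus_id]
            if k != unrestricted_k and len(members) not in allowed:
                continue
            selected.append(pick_representative(members, frac))
    return selected


def trinity_select(
    records: Sequence[IsoformRecord], mode: str = "pickH"
) -> list[IsoformRecord]:
    """Trinity-style isoform selection by expression share.

    ``pickH`` keeps exactly the highest-IsoPct isoform per subcomponent
    (ties: longer, then lexicographic id); ``removeL`` drops exactly the
    lowest-IsoPct isoform from each subcomponent holding two or more.
    """
    if mode not in ("pickH", "removeL"):
        raise ConfigError(f"mode must be 'pickH' or 'removeL', got {mode!r}")
    groups: dict[tuple[str, str], list[IsoformRecord]] = {}
    for r in records:
        groups.setdefault((r.component_id, r.subcomponent_id), []).append(r)

    out: list[IsoformRecord] = []
    for key in sorted(groups):
        members = groups[key]
        if mode == "pickH":
            out.append(
                min(members, key=lambda r: (-r.iso_pct, -r.length, r.isoform_id))
            )
        else:
            if len(members) < 2:
                out.extend(members)
                continue
            lowest = min(members, key=lambda r: (r.iso_pct, r.length, r.isoform_id))
            out.extend(r for r in members if r is not lowest)
    return out


# ---------------------------------------------------------------------------
# tabular I/O

LOCUS_TABLE_COLUMNS = ["locus_id", "transcript_id", "length", "k", "node_coverages"]
ISOFORM_TABLE_COLUMNS = [
    "component_id",
    "subcomponent_id",
    "isoform_id",
    "iso_pct",
    "length",
]


def read_locus_table(path) -> list[LocusTranscript]:
    """Read the sidecar TSV: locus, transcript, length, k, comma-joined
    node coverages.  Keeps the module assembler-agnostic — Oases versions
    disagree about where node coverages live."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(LOCUS_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"locus table missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LocusTranscript(
                locus_id=row.locus_id,
                transcript_id=row.transcript_id,
                length=int(row.length),
                node_coverages=tuple(float(x) for x in str(row.node_coverages).split(",")),
                k=int(row.k),
            )
        )
    return out


def write_locus_table(records: Iterable[LocusTranscript], path) -> None:
    rows = [
        {
            "locus_id": t.locus_id,
            "transcript_id": t.transcript_id,
            "length": t.length,
            "k": t.k,
            "node_coverages": ",".join(f"{c:g}" for c in t.node_coverages),
        }
        for t in records
    ]
    pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_isoform_table(path) -> list[IsoformRecord]:
    """Read the Trinity/RSEM-style isoform table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ISOFORM_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"isoform table missing column(s): {sorted(missing)}")
    return [
        IsoformRecord(
            component_id=row.component_id,
            subcomponent_id=row.subcomponent_id,
            isoform_id=row.isoform_id,
            iso_pct=float(row.iso_pct),
            length=int(row.length),
        )
        for row in df.itertuples(index=False)
    ]


def write_isoform_table(records: Iterable[IsoformRecord], path) -> None:
    rows = [
        {
            "component_id": r.component_id,
            "subcomponent_id": r.subcomponent_id,
            "isoform_id": r.isoform_id,
            "iso_pct": r.iso_pct,
            "length": r.length,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ISOFORM_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
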