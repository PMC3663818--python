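"""Reference-based chimera detection, classification, and assembly metrics.

Assembled transcripts are aligned to a non-redundant reference transcript set
(BLAT, PSL output).  After discarding weak hits, each query is classified:

* one hit — non-chimeric, that hit is the best hit;
* several hits — the hit with the most matching bases is the best hit; the
  query is a chimera if any remaining hit's query coverage has no, or
  minimal, overlap with the best hit's (under 60 bp AND under 20% of the
  shorter of the pair).  Otherwise the longest hit becomes the best hit and
  the query is non-chimeric.

A chimera is typed on two axes: the two evidence hits share a target
(*self*) or not (*multi-gene*), and share a strand (*cis*) or not (*trans*).

The same module computes the assembly-level report: per-reference coverage
from best hits of non-chimeric queries, the three coverage percentages, the
chimera rate, and redundancy (queries with hits / references with hits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from transqc.seqformats import (
    DataError,
    Hit,
    Interval,
    Thresholds,
    is_minimal_overlap,
    union_length,
)

CHIMERA_TYPES = ("cis_self", "cis_multi", "trans_self", "trans_multi")


@dataclass(frozen=True)
class ChimeraCall:
    """Verdict on one assembled transcript."""

    query_id: str
    is_chimera: bool
    chimera_type: str  # one of CHIMERA_TYPES or "none"
    best_hit: Hit | None = None
    evidence: tuple[Hit, Hit] | None = None

    def __post_init__(self) -> None:
        if self.is_chimera != (self.chimera_type != "none"):
            raise ValueError("chimera_type must be 'none' iff not a chimera")


@dataclass(frozen=True)
class CoverageReport:
    """Assembly-level coverage, redundancy and chimera-rate summary."""

    pct_ref_bp: float
    pct_genes_gt200: float
    pct_genes_ge80: float
    redundancy: float
    chimera_rate: float
    n_queries_with_hits: int
    n_refs_with_hits: int


def filter_hits(hits: Iterable[Hit], t: Thresholds) -> list[Hit]:
    """Discard hits below the similarity or matching-base cutoffs."""
    return [
        h
        for h in hits
        if h.percent_identity >= t.min_blat_identity and h.matches >= t.min_blat_matches
    ]


def _hit_order(h: Hit) -> tuple:
    # most matches first, then longest query coverage, then stable ids
    return (-h.matches, -len(h.q_interval), h.target_id, h.q_interval.start, h.strand)


def classify_query(hits: Sequence[Hit], t: Thresholds) -> ChimeraCall:
    """Classify one query's (already filtered) hits.

    The result is invariant under permutation of ``hits``: candidates are
    re-sorted internally by matches, then query-coverage length, then
    target id.
    """
    if not hits:
        raise ValueError("classify_query requires at least one hit")
    qid = hits[0].query_id
    if any(h.query_id != qid for h in hits):
        raise DataError("classify_query received hits from multiple queries")

    if len(hits) == 1:
        return ChimeraCall(qid, False, "none", best_hit=hits[0])

    ordered = sorted(hits, key=_hit_order)
    best = ordered[0]
    for other in ordered[1:]:
        if is_minimal_overlap(best.q_interval, other.q_interval, t):
            same_target = other.target_id == best.target_id
            same_strand = other.strand == best.strand
            ctype = ("cis" if same_strand else "trans") + (
                "_self" if same_target else "_multi"
            )
            return ChimeraCall(qid, True, ctype, best_hit=best, evidence=(best, other))
    longest = min(ordered, key=lambda h: (-len(h.q_interval), -h.matches, h.target_id))
    return ChimeraCall(qid, False, "none", best_hit=longest)


def classify_all(hits: Iterable[Hit], t: Thresholds) -> list[ChimeraCall]:
    """Filter hits and classify every query that retains at least one hit."""
    kept = filter_hits(hits, t)
    by_query: dict[str, list[Hit]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    return [classify_query(qhits, t) for _, qhits in sorted(by_query.items())]


def remove_organellar_refs(
    organelle_hits: Iterable[Hit],
    ref_lengths: Mapping[str, int],
    t: Thresholds,
) -> set[str]:
    """Drop references that are essentially organellar sequence.

    A reference is removed when the union ("combined region", overlapping
    bases counted once) of its query coverages from hits at
    >= ``organellar_identity`` similarity spans >= ``organellar_cov_frac``
    of its length.  Returns the retained reference ids.
    """
    cov: dict[str, list[Interval]] = {}
    for h in organelle_hits:
        if h.query_id not in ref_lengths:
            raise DataError(f"reference {h.query_id!r} missing from ref_lengths")
        if h.percent_identity >= t.organellar_identity:
            cov.setdefault(h.query_id, []).append(h.q_interval)
    removed = {
        rid
        for rid, ivs in cov.items()
        if union_length(ivs) >= t.organellar_cov_frac * ref_lengths[rid]
    }
    return set(ref_lengths) - removed


def coverage_report(
    calls: Sequence[ChimeraCall],
    all_hits: Sequence[Hit],
    ref_lengths: Mapping[str, int],
    t: Thresholds,
) -> CoverageReport:
    """Assembly-level metrics from per-query calls and the filtered hit set.

    Per reference, coverage is the longest target interval among best hits
    of non-chimeric queries (one sequence per gene downstream, so only the
    single best representative counts).  Chimeric queries contribute no
    coverage but do count as "assembled sequences with hits" in redundancy.
    """
    per_ref_cov: dict[str, int] = {}
    for call in calls:
        if call.is_chimera or call.best_hit is None:
            continue
        h = call.best_hit
        cov = len(h.t_interval)
        if cov > per_ref_cov.get(h.target_id, 0):
            per_ref_cov[h.target_id] = cov

    n_refs = len(ref_lengths)
    total_ref_bp = sum(ref_lengths.values())
    covered_bp = sum(
        cov for cov in per_ref_cov.values() if cov > t.min_transcript_len
    )
    n_gt200 = sum(1 for cov in per_ref_cov.values() if cov > t.min_transcript_len)
    n_ge80 = sum(
        1
        for rid, cov in per_ref_cov.items()
        if cov >= 0.8 * ref_lengths[rid]
    )

    n_queries = len({h.query_id for h in all_hits})
    n_refs_hit = len({h.target_id for h in all_hits})
    n_chimeric = sum(1 for c in calls if c.is_chimera)

    return CoverageReport(
        pct_ref_bp=100.0 * covered_bp / total_ref_bp if total_ref_bp else 0.0,
        pct_genes_gt200=100.0 * n_gt200 / n_refs if n_refs else 0.0,
        pct_genes_ge80=100.0 * n_ge80 / n_refs if n_refs else 0.0,
        redundancy=n_queries / n_refs_hit if n_refs_hit else math.nan,
        chimera_rate=100.0 * n_chimeric / len(calls) if calls else 0.0,
        n_queries_with_hits=n_queries,
        n_refs_with_hits=n_refs_hit,
    )


def calls_to_rows(calls: Iterable[ChimeraCall]) -> list[dict]:
    """Flatten calls for TSV/JSON reporting."""
    rows = []
    for c in calls:
        row = {
            "query_id": c.query_id,
            "is_chimera": c.is_chimera,
            "chimera_type": c.chimera_type,
            "best_target": c.best_hit.target_id if c.best_hit else "",
            "best_q_start": c.best_hit.q_interval.start if c.best_hit else "",
            "best_q_end": c.best_hit.q_interval.end if c.best_hit else "",
        }
        if c.evidence:
            row["evidence_target"] = c.evidence[1].target_id
            row["evidence_q_start"] = c.evidence[1].q_interval.start
            row["evidence_q_end"] = c.evidence[1].q_interval.end
        else:
            row["evidence_target"] = ""
            row["evidence_q_start"] = ""
            row["evidence_q_end"] = ""
        rows.append(row)
    return rows
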