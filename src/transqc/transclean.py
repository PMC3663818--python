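"""Reference-free trans-chimera detection and cutting from translated-search
HSPs.

A transcript carrying two long, non-overlapping ORF regions read in opposite
directions — each similar to known proteins — is almost certainly a
trans-chimera in a eukaryotic nuclear transcriptome.  The procedure:

1. drop HSPs with identity below 30% or query coverage shorter than 100 bp;
2. per query-target pair (strongest pair first): if both directions occur,
   merge same-direction query coverages into one span each ("one ORF per
   direction"); if the plus and minus spans pass the minimal-overlap rule
   the query is a *trans-self* chimera — keep only the longer span and stop
   looking at this query;
3. queries with no trans-self call are re-checked with spans merged across
   *all* targets; a passing overlap test there is a *trans-multi-gene* call.

Called transcripts are cut down to the retained span; anything not longer
than 200 bp after cutting is dropped.  Cis chimeras are deliberately left
alone: against distant model proteomes, tandem duplication and rate
heterogeneity mimic cis-chimeric hit patterns too easily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from transqc.seqformats import (
    DataError,
    HSPRecord,
    Interval,
    Thresholds,
    is_minimal_overlap,
    span,
)


@dataclass(frozen=True)
class TransCall:
    """Outcome of trans-chimera screening for one query transcript."""

    query_id: str
    call_type: str  # "trans_self", "trans_multi", or "none"
    plus_span: Interval | None = None
    minus_span: Interval | None = None
    retained: Interval | None = None
    target_id: str | None = None  # trans_self only


def filter_hsps(hsps: Iterable[HSPRecord], t: Thresholds) -> list[HSPRecord]:
    """Discard HSPs below the identity or query-coverage cutoffs."""
    return [
        h
        for h in hsps
        if h.percent_identity >= t.min_hsp_identity
        and len(h.q_interval) >= t.min_hsp_qcov
    ]


def merge_directional(
    hsps: Sequence[HSPRecord],
) -> tuple[Interval | None, Interval | None]:
    """Merge same-direction query coverages into one span per direction.

    Same-direction HSPs are usually fragments of a single ORF split by
    indels, so the merged coverage is the min-start/max-end span, not the
    interval union.
    """
    plus = [h.q_interval for h in hsps if h.direction == "plus"]
    minus = [h.q_interval for h in hsps if h.direction == "minus"]
    return (span(plus) if plus else None, span(minus) if minus else None)


def _pick_retained(
    plus_span: Interval, minus_span: Interval
) -> Interval:
    # longer span wins; on a tie the plus span is retained
    if len(minus_span) > len(plus_span):
        return minus_span
    return plus_span


def detect_trans_self(hsps: Sequence[HSPRecord], t: Thresholds) -> TransCall:
    """Trans-self screening: both directions against one target.

    Query-target pairs are visited strongest first (descending best
    bitscore, ties by target id); the first pair whose plus and minus spans
    pass the minimal-overlap rule yields the call and all later pairs are
    ignored.
    """
    if not hsps:
        return TransCall("", "none")
    qid = hsps[0].query_id
    by_target: dict[str, list[HSPRecord]] = {}
    for h in hsps:
        if h.query_id != qid:
            raise DataError("detect_trans_self received hits from multiple queries")
        by_target.setdefault(h.target_id, []).append(h)

    order = sorted(
        by_target, key=lambda tid: (-max(h.bitscore for h in by_target[tid]), tid)
    )
    for tid in order:
        plus_span, minus_span = merge_directional(by_target[tid])
        if plus_span is None or minus_span is None:
            continue  # single-direction pair: no trans evidence here
        if is_minimal_overlap(plus_span, minus_span, t):
            return TransCall(
                qid,
                "trans_self",
                plus_span=plus_span,
                minus_span=minus_span,
                retained=_pick_retained(plus_span, minus_span),
                target_id=tid,
            )
    return TransCall(qid, "none")


def detect_trans_multi(hsps: Sequence[HSPRecord], t: Thresholds) -> TransCall:
    """Trans-multi screening: directional spans merged across all targets.

    Only meaningful for queries where :func:`detect_trans_self` returned
    no call.
    """
    if not hsps:
        return TransCall("", "none")
    qid = hsps[0].query_id
    plus_span, minus_span = merge_directional(hsps)
    if plus_span is None or minus_span is None:
        return TransCall(qid, "none")
    if is_minimal_overlap(plus_span, minus_span, t):
        return TransCall(
            qid,
            "trans_multi",
            plus_span=plus_span,
            minus_span=minus_span,
            retained=_pick_retained(plus_span, minus_span),
        )
    return TransCall(qid, "none")


def detect_query(hsps: Sequence[HSPRecord], t: Thresholds) -> TransCall:
    """Full screening for one query: trans-self first, then trans-multi."""
    call = detect_trans_self(hsps, t)
    if call.call_type != "none":
        return call
    return detect_trans_multi(hsps, t)


def detect_all(hsps: Iterable[HSPRecord], t: Thresholds) -> list[TransCall]:
    """Filter HSPs and screen every query that retains at least one."""
    kept = filter_hsps(hsps, t)
    by_query: dict[str, list[HSPRecord]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    return [detect_query(qhits, t) for _, qhits in sorted(by_query.items())]


def cut_and_filter(
    sequences: Mapping[str, str],
    calls: Sequence[TransCall],
    t: Thresholds,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Cut called transcripts to their retained span; drop short output.

    Returns ``(records, report_rows)`` where records are ``(name, seq)``
    pairs ready for FASTA output.  A called transcript's output name carries
    the retained coordinates (``id:start-end``); untouched sequences pass
    through verbatim.  A cut sequence not longer than ``min_transcript_len``
    is dropped.
    """
    call_by_query: dict[str, TransCall] = {}
    for c in calls:
        if c.call_type != "none":
            if c.query_id not in sequences:
                raise DataError(f"call references unknown sequence {c.query_id!r}")
            call_by_query[c.query_id] = c

    records: list[tuple[str, str]] = []
    rows: list[dict] = []
    for name, seq in sequences.items():
        call = call_by_query.get(name)
        if call is None:
            records.append((name, seq))
            continue
        kept = seq[call.retained.start : call.retained.end]
        rows.append(
            {
                "query_id": name,
                "call_type": call.call_type,
                "plus_span": f"{call.plus_span.start}-{call.plus_span.end}",
                "minus_span": f"{call.minus_span.start}-{call.minus_span.end}",
                "retained": f"{call.retained.start}-{call.retained.end}",
                "target_id": call.target_id or "",
                "kept": len(kept) > t.min_transcript_len,
            }
        )
        if len(kept) > t.min_transcript_len:
            records.append((f"{name}:{call.retained.start}-{call.retained.end}", kept))
    return records, rows
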