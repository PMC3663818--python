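"""Reference-based chimera classification and the coverage/redundancy report."""

import math
import random

import pytest

from transqc.refeval import (
    ChimeraCall,
    classify_all,
    classify_query,
    coverage_report,
    filter_hits,
    remove_organellar_refs,
)
from transqc.seqformats import DataError, Hit, Interval, Thresholds


def make_hit(
    query="q1", target="r1", strand="+", q=(0, 400), t=(0, 400),
    matches=None, mismatches=0, qlen=1000, tlen=1000,
):
    if matches is None:
        matches = q[1] - q[0] - mismatches
    return Hit(
        query_id=query, target_id=target, strand=strand,
        q_interval=Interval(*q), t_interval=Interval(*t),
        matches=matches, mismatches=mismatches,
        query_length=qlen, target_length=tlen,
    )


class TestFilterHits:
    def test_identity_boundary(self, thresholds):
        low = make_hit(matches=949, mismatches=51, q=(0, 1000))  # 94.9%
        keep = make_hit(matches=950, mismatches=50, q=(0, 1000))  # 95.0%
        assert filter_hits([low, keep], thresholds) == [keep]

    def test_matches_boundary(self, thresholds):
        low = make_hit(q=(0, 99), t=(0, 99), matches=99)  # 100% identity, 99 matches
        keep = make_hit(q=(0, 100), t=(0, 100), matches=100)
        assert filter_hits([low, keep], thresholds) == [keep]


class TestClassifyQuery:
    def test_single_hit_is_non_chimeric(self, thresholds):
        hit = make_hit()
        call = classify_query([hit], thresholds)
        assert not call.is_chimera
        assert call.chimera_type == "none" and call.best_hit == hit

    def test_trans_self(self, thresholds):
        a = make_hit(q=(0, 400), t=(0, 400), strand="+")
        b = make_hit(q=(420, 800), t=(500, 880), strand="-")
        call = classify_query([a, b], thresholds)
        assert call.is_chimera and call.chimera_type == "trans_self"

    def test_cis_multi_with_small_overlap(self, thresholds):
        a = make_hit(q=(0, 500), t=(0, 500), target="rA")
        b = make_hit(q=(480, 900), t=(0, 420), target="rB")
        # overlap 20 < 60 and < 0.2*420
        call = classify_query([a, b], thresholds)
        assert call.chimera_type == "cis_multi"
        assert call.evidence[0].target_id != call.evidence[1].target_id

    def test_cis_self_and_trans_multi(self, thresholds):
        cis = classify_query(
            [make_hit(q=(0, 400), t=(0, 400)), make_hit(q=(450, 800), t=(600, 950))],
            thresholds,
        )
        assert cis.chimera_type == "cis_self"
        trans = classify_query(
            [
                make_hit(q=(0, 400), t=(0, 400), target="rA"),
                make_hit(q=(450, 800), t=(0, 350), target="rB", strand="-"),
            ],
            thresholds,
        )
        assert trans.chimera_type == "trans_multi"

    def test_large_overlap_is_non_chimeric_longest_best(self, thresholds):
        a = make_hit(q=(0, 500), t=(0, 500))
        b = make_hit(q=(100, 650), t=(50, 600), matches=540, mismatches=10)
        call = classify_query([a, b], thresholds)
        assert not call.is_chimera
        assert call.best_hit == b  # longest query interval wins when no chimera

    def test_permutation_invariance(self, thresholds):
        hits = [
            make_hit(q=(0, 400), t=(0, 400), target="rA"),
            make_hit(q=(420, 800), t=(100, 480), target="rB"),
            make_hit(q=(50, 350), t=(60, 360), target="rC"),
        ]
        rng = random.Random(0)
        baseline = classify_query(hits, thresholds)
        for _ in range(20):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            assert classify_query(shuffled, thresholds) == baseline

    def test_empty_input_is_error(self, thresholds):
        with pytest.raises(ValueError):
            classify_query([], thresholds)

    def test_mixed_queries_rejected(self, thresholds):
        with pytest.raises(DataError):
            classify_query([make_hit(query="a"), make_hit(query="b")], thresholds)


class TestOrganellarRemoval:
    def test_union_coverage_removal(self, thresholds):
        hits = [
            make_hit(query="ref1", target="chloro", q=(0, 500)),
            make_hit(query="ref1", target="chloro", q=(450, 900)),
        ]
        retained = remove_organellar_refs(hits, {"ref1": 1000, "ref2": 500}, thresholds)
        assert retained == {"ref2"}  # union 900 >= 800

    def test_799_of_1000_retained(self, thresholds):
        hits = [make_hit(query="ref1", target="chloro", q=(0, 799))]
        retained = remove_organellar_refs(hits, {"ref1": 1000}, thresholds)
        assert retained == {"ref1"}

    def test_low_identity_hits_ignored(self, thresholds):
        hits = [
            make_hit(query="ref1", target="chloro", q=(0, 1000),
                     matches=900, mismatches=100)  # 90% identity
        ]
        assert remove_organellar_refs(hits, {"ref1": 1000}, thresholds) == {"ref1"}

    def test_unknown_reference_is_data_error(self, thresholds):
        with pytest.raises(DataError):
            remove_organellar_refs([make_hit(query="ghost")], {"ref1": 100}, thresholds)


# ---------------------------------------------------------------------------
# coverage report: hand toy + brute-force oracle


def brute_force_report(calls, hits, ref_lengths, t):
    """Independent naive recomputation by direct nested iteration."""
    pct = {}
    n_gt200 = n_ge80 = covered_bp = 0
    for rid, rlen in ref_lengths.items():
        best = 0
        for call in calls:
            if call.is_chimera or call.best_hit is None:
                continue
            if call.best_hit.target_id == rid:
                cov = call.best_hit.t_interval.end - call.best_hit.t_interval.start
                best = max(best, cov)
        if best > t.min_transcript_len:
            n_gt200 += 1
            covered_bp += best
        if best >= 0.8 * rlen:
            n_ge80 += 1
    n_refs = len(ref_lengths)
    queries = {h.query_id for h in hits}
    targets = {h.target_id for h in hits}
    n_chim = len([c for c in calls if c.is_chimera])
    return {
        "pct_ref_bp": 100.0 * covered_bp / sum(ref_lengths.values()),
        "pct_genes_gt200": 100.0 * n_gt200 / n_refs,
        "pct_genes_ge80": 100.0 * n_ge80 / n_refs,
        "redundancy": len(queries) / len(targets) if targets else math.nan,
        "chimera_rate": 100.0 * n_chim / len(calls) if calls else 0.0,
    }


def random_instance(rng: random.Random, t: Thresholds):
    n_refs = rng.randint(1, 50)
    n_queries = rng.randint(1, 100)
    ref_lengths = {f"r{i}": rng.randint(250, 3000) for i in range(n_refs)}
    hits, calls = [], []
    for qi in range(n_queries):
        rid = rng.choice(list(ref_lengths))
        rlen = ref_lengths[rid]
        tstart = rng.randint(0, rlen - 150)
        tend = rng.randint(tstart + 100, rlen)
        h = make_hit(
            query=f"q{qi}", target=rid, q=(0, tend - tstart), t=(tstart, tend),
            tlen=rlen, qlen=tend - tstart,
        )
        hits.append(h)
        if rng.random() < 0.2:  # random chimera flag
            calls.append(ChimeraCall(f"q{qi}", True, "cis_multi", best_hit=h,
                                     evidence=(h, h)))
        else:
            calls.append(ChimeraCall(f"q{qi}", False, "none", best_hit=h))
    return calls, hits, ref_lengths


class TestCoverageReport:
    def test_hand_toy(self, thresholds):
        ref_lengths = {"rA": 1000, "rB": 1000}
        h = make_hit(query="q1", target="rA", q=(0, 1000), t=(0, 1000), tlen=1000)
        calls = [ChimeraCall("q1", False, "none", best_hit=h)]
        rep = coverage_report(calls, [h], ref_lengths, thresholds)
        assert rep.pct_genes_gt200 == 50.0
        assert rep.pct_ref_bp == 50.0
        assert rep.pct_genes_ge80 == 50.0
        assert rep.redundancy == 1.0
        assert rep.chimera_rate == 0.0

    def test_all_chimeric(self, thresholds):
        h = make_hit(query="q1")
        calls = [ChimeraCall("q1", True, "cis_self", best_hit=h, evidence=(h, h))]
        rep = coverage_report(calls, [h], {"r1": 1000}, thresholds)
        assert rep.pct_ref_bp == rep.pct_genes_gt200 == rep.pct_genes_ge80 == 0.0
        assert rep.chimera_rate == 100.0

    def test_chimera_plus_nonchimera_rates_sum_to_100(self, thresholds, scenario,
                                                      scenario_hits):
        kept = filter_hits(scenario_hits, thresholds)
        calls = classify_all(scenario_hits, thresholds)
        rep = coverage_report(calls, kept, scenario.ref_lengths, thresholds)
        non_chimeric = 100.0 * sum(1 for c in calls if not c.is_chimera) / len(calls)
        assert rep.chimera_rate + non_chimeric == pytest.approx(100.0)

    def test_matches_brute_force_oracle_on_random_instances(self, thresholds):
        rng = random.Random(1234)
        for _ in range(200):
            calls, hits, ref_lengths = random_instance(rng, thresholds)
            rep = coverage_report(calls, hits, ref_lengths, thresholds)
            expected = brute_force_report(calls, hits, ref_lengths, thresholds)
            assert rep.pct_ref_bp == pytest.approx(expected["pct_ref_bp"], abs=1e-9)
            assert rep.pct_genes_gt200 == pytest.approx(
                expected["pct_genes_gt200"], abs=1e-9
            )
            assert rep.pct_genes_ge80 == pytest.approx(
                expected["pct_genes_ge80"], abs=1e-9
            )
            assert rep.redundancy == pytest.approx(expected["redundancy"], abs=1e-9)
            assert rep.chimera_rate == pytest.approx(
                expected["chimera_rate"], abs=1e-9
            )


def test_ground_truth_confusion_matrix_exact(thresholds, scenario, scenario_hits):
    """On synthetic data with above-threshold components, classification
    recovers every injected chimera and its type, and flags no clean one."""
    calls = {c.query_id: c for c in classify_all(scenario_hits, thresholds)}
    for rec in scenario.truth:
        call = calls[rec.transcript_id]
        if rec.chimera_type == "none":
            assert not call.is_chimera, rec.transcript_id
        else:
            assert call.is_chimera, rec.transcript_id
            assert call.chimera_type == rec.chimera_type
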