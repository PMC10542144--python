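"""Overlap resolution, split-hit merging and architecture flags."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cheascope as cs
from cheascope.architecture import (
    build_architecture,
    build_records,
    classify_chea,
    locate_cheY_like,
    merge_split_hits,
    resolve_overlaps,
)
from cheascope.models import CHEC_LIKE, CHEW, CHEY_LIKE, DIM, HATPASE, HPT, P2
from cheascope.scan import DomainHit

from conftest import zero_perturbation


def H(family, start, end, score=1.0, **kw):
    return DomainHit("p", family, start, end, score, **kw)


# -- resolve_overlaps --------------------------------------------------------

def test_disjoint_hits_unchanged():
    hits = [H(HPT, 0, 90), H(P2, 100, 170)]
    assert resolve_overlaps(hits) == sorted(hits, key=lambda h: h.start)


def test_full_overlap_keeps_higher_score():
    a, b = H(HPT, 0, 90, 0.9), H(P2, 10, 80, 0.7)
    assert resolve_overlaps([a, b]) == [a]


def _greedy_oracle(hits):
    """Independent characterization: among all maximal disjoint subsets,
    the greedy result is the lexicographic maximum under the priority
    key sequence (score desc, start asc, family asc)."""
    def key(h):
        return (-h.score, h.start, h.family_name)

    best = None
    n = len(hits)
    for mask in range(2 ** n):
        subset = [hits[i] for i in range(n) if mask >> i & 1]
        if any(a.overlaps(b) for a, b in itertools.combinations(subset, 2)):
            continue
        # maximality: no remaining hit can be added
        if any(
            all(not h.overlaps(s) for s in subset) for h in hits if h not in subset
        ):
            continue
        sig = sorted(key(h) for h in subset)
        if best is None or sig < best[0]:
            best = (sig, subset)
    return sorted(best[1], key=lambda h: h.start)


def test_resolution_matches_exhaustive_subset_oracle():
    """Random <=8-hit instances versus brute-force enumeration."""
    rng = np.random.default_rng(99)
    fams = [HPT, P2, CHEW, HATPASE]
    for _ in range(40):
        n = int(rng.integers(1, 9))
        hits = []
        for _ in range(n):
            s = int(rng.integers(0, 200))
            e = s + int(rng.integers(20, 120))
            hits.append(
                H(fams[int(rng.integers(0, 4))], s, e, round(float(rng.uniform(0.4, 1.0)), 3))
            )
        assert resolve_overlaps(hits) == _greedy_oracle(hits)


def test_resolve_is_idempotent():
    rng = np.random.default_rng(5)
    hits = [H(HPT, int(s), int(s) + 60, float(sc)) for s, sc in
            zip(rng.integers(0, 300, 10), rng.uniform(0.4, 1, 10))]
    once = resolve_overlaps(hits)
    assert resolve_overlaps(once) == once


# -- merge_split_hits --------------------------------------------------------

def test_split_chew_fragments_merge():
    """Two CheW fragments 50 apart collapse to one domain; a protein with
    an additional intact CheW reports two copies, not three."""
    hits = [
        H(CHEW, 100, 150, partial=True),
        H(CHEW, 200, 250, partial=True),  # gap 50 (the insertion)
        H(CHEW, 320, 420),  # genuine second copy
    ]
    merged = merge_split_hits(hits)
    assert [(h.start, h.end, h.merged_from) for h in merged] == [
        (100, 250, 2),
        (320, 420, 1),
    ]
    rec = build_architecture("p", "F5", merged)
    assert rec.count(CHEW) == 2


def test_fragments_beyond_gap_not_merged():
    hits = [H(CHEW, 0, 100), H(CHEW, 180, 280)]  # gap 80 > 60
    assert merge_split_hits(hits) == hits


def test_genuine_tandem_duplication_protected_by_length_guard():
    # gap 30 <= 60 but merged span 230 exceeds max_len + gap
    hits = [H(CHEW, 0, 100), H(CHEW, 130, 230)]
    assert merge_split_hits(hits) == hits


def test_merge_never_crosses_intervening_family():
    """CheW–CheY-like–CheW stays three domains (the T. roseum pattern)."""
    hits = [
        H(CHEW, 0, 50, partial=True),
        H(CHEY_LIKE, 55, 170),
        H(CHEW, 175, 225, partial=True),
    ]
    merged = merge_split_hits(hits)
    assert [h.family_name for h in merged] == [CHEW, CHEY_LIKE, CHEW]


def test_merge_is_idempotent():
    hits = [H(CHEW, 100, 150), H(CHEW, 200, 250), H(HPT, 300, 390)]
    once = merge_split_hits(hits)
    assert merge_split_hits(once) == once


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 400), min_size=0, max_size=6), st.integers(0, 3))
def test_merge_preserves_coverage_and_order(starts, fam_idx):
    fams = [HPT, CHEW, P2, CHEY_LIKE]
    starts = sorted(set(starts))
    hits = []
    prev_end = -1
    for s in starts:
        if s <= prev_end:
            continue
        e = s + 50
        hits.append(H(fams[fam_idx], s, e, 0.9))
        prev_end = e
    merged = merge_split_hits(hits)
    # disjoint, sorted, copy conservation
    assert merged == sorted(merged, key=lambda h: h.start)
    for a, b in zip(merged, merged[1:]):
        assert a.end <= b.start
    assert sum(h.merged_from for h in merged) == len(hits)
    if hits:
        assert merged[0].start == hits[0].start and merged[-1].end == hits[-1].end


# -- build_architecture / flags ----------------------------------------------

def _canonical_hits():
    return [
        H(HPT, 20, 110),
        H(P2, 130, 200),
        H(DIM, 220, 280),
        H(HATPASE, 300, 410),
        H(CHEW, 430, 530),
    ]


def test_canonical_five_flag():
    rec = build_architecture("p", "F1", _canonical_hits())
    assert rec.flags["canonical_five"]
    assert not rec.flags["lacks_P2"]
    assert not rec.flags["multi_Hpt"]
    assert not rec.flags["cheY_like_present"]
    assert rec.arch_string == "Hpt,P2,H-kinase_dim,HATPase_c,CheW"


def test_multi_hpt_no_p2_with_chey():
    hits = [H(HPT, 0, 90), H(HPT, 110, 200), H(HPT, 220, 310),
            H(DIM, 330, 390), H(HATPASE, 400, 510), H(CHEW, 530, 630),
            H(CHEY_LIKE, 650, 765)]
    rec = build_architecture("p", "Tfp", hits)
    f = rec.flags
    assert f["multi_Hpt"] and f["lacks_P2"] and f["cheY_like_present"]
    assert not f["canonical_five"]


def test_chec_fusion_flag():
    hits = _canonical_hits() + [H(CHEC_LIKE, 550, 650)]
    rec = build_architecture("p", "F1", hits)
    assert rec.flags["has_cheC_fusion"]


def test_dim_extended_flag_boundary():
    short = build_architecture("p", "F1", [H(DIM, 0, 70), H(HATPASE, 80, 190), H(CHEW, 200, 300)])
    long = build_architecture("p", "F1", [H(DIM, 0, 71), H(HATPASE, 80, 190), H(CHEW, 200, 300)])
    assert not short.flags["dim_extended"]
    assert long.flags["dim_extended"]


def test_classify_chea_requires_core_pair():
    full = build_architecture("p", "F1", _canonical_hits())
    chew_only = build_architecture("p", "F1", [H(CHEW, 0, 100)])
    hat_only = build_architecture("p", "F1", [H(HATPASE, 0, 110)])
    assert classify_chea(full) == "cheA"
    assert classify_chea(chew_only) == "not_cheA"
    assert classify_chea(hat_only) == "not_cheA"


def test_locate_chey_like_positions():
    c_term = build_architecture("p", "F5", [H(CHEW, 0, 100), H(HATPASE, 110, 220), H(CHEY_LIKE, 240, 355)])
    n_term = build_architecture("p", "F3", [H(CHEY_LIKE, 0, 115), H(HPT, 130, 220), H(HATPASE, 240, 350), H(CHEW, 360, 460)])
    internal = build_architecture(
        "p", "F1",
        [H(HATPASE, 0, 110), H(CHEW, 120, 220), H(CHEY_LIKE, 230, 345), H(CHEW, 350, 450), H(CHEW, 470, 570)],
    )
    absent = build_architecture("p", "F1", _canonical_hits())
    assert locate_cheY_like(c_term) == {"C_terminal"}
    assert locate_cheY_like(n_term) == {"N_terminal"}
    assert locate_cheY_like(internal) == {"internal"}
    assert locate_cheY_like(absent) == "absent"


def test_copy_counts_conserve_domains():
    rec = build_architecture("p", "F5", _canonical_hits() + [H(CHEW, 550, 650)])
    assert sum(rec.copy_counts.values()) == len(rec.domains)


# -- ground-truth agreement --------------------------------------------------

def test_zero_perturbation_architecture_equals_template(small_clean_cohort):
    cohort = small_clean_cohort
    classes = {r.protein_id: r.class_label for r in cohort.truth}
    from cheascope.pipeline import analyze_cohort

    _, records = analyze_cohort(cohort.sequences, classes, cs.ScanConfig(), cs.BuilderConfig())
    truth = {r.protein_id: r for r in cohort.truth}
    for rec in records:
        assert rec.families == truth[rec.protein_id].families()


def test_forced_split_chew_counts_restored(default_config):
    """With split_prob = 1, merging restores the template CheW count in
    >= 99% of records."""
    cfg = zero_perturbation(default_config).replace(split_prob=1.0)
    cohort = cs.generate_cohort(cfg, 300, seed=21)
    classes = {r.protein_id: r.class_label for r in cohort.truth}
    from cheascope.pipeline import analyze_cohort

    _, records = analyze_cohort(cohort.sequences, classes, cs.ScanConfig(), cs.BuilderConfig())
    truth = {r.protein_id: r for r in cohort.truth}
    ok = sum(
        rec.count(CHEW) == truth[rec.protein_id].families().count(CHEW) for rec in records
    )
    assert ok / len(records) >= 0.99
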