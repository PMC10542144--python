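"""Two-tier scanner: exact recovery, rescue boundary, hit-table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cheascope as cs
from cheascope import io as cio
from cheascope.models import CHEW, DIM, HATPASE, HPT, LINKER_ALPHABET, P2
from cheascope.scan import (
    DomainHit,
    scan_sensitive,
    scan_standard,
    scan_two_tier,
    uncovered_regions,
)


def _degrade_to_half(consensus: str, rng=None) -> str:
    """Substitute every second residue: identity ~0.5 on any window."""
    rng = rng or np.random.default_rng(0)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(consensus)
    for i in range(0, len(out), 2):
        choices = [c for c in aa if c != out[i]]
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _linker(n: int) -> str:
    return (LINKER_ALPHABET * (n // len(LINKER_ALPHABET) + 1))[:n]


def test_zero_perturbation_hits_equal_truth(small_clean_cohort, models):
    """On unperturbed cohorts every true domain yields exactly one
    standard hit with ground-truth coordinates (generator inversion)."""
    cohort = small_clean_cohort
    mlist = list(models.values())
    for row in cohort.truth[:150]:
        hits = scan_standard(cohort.sequences[row.protein_id], mlist, protein_id=row.protein_id)
        got = [(h.family_name, h.start, h.end) for h in hits]
        want = [(d.family, d.start, d.end) for d in row.true_domains]
        assert got == want


def test_empty_sequence_yields_no_hits(models):
    assert scan_standard("", list(models.values())) == []


def test_degraded_domain_invisible_to_standard_tier(models):
    hpt = models[HPT]
    seq = _linker(20) + _degrade_to_half(hpt.consensus) + _linker(20)
    hits = scan_standard(seq, [hpt])
    assert hits == []


def test_degraded_domain_found_by_sensitive_tier(models):
    p2 = models[P2]
    seq = _linker(25) + _degrade_to_half(p2.consensus) + _linker(25)
    hits = scan_sensitive(seq, (0, len(seq)), [p2])
    assert len(hits) == 1
    assert hits[0].family_name == P2
    assert hits[0].mode == "sensitive"
    assert 0.40 <= hits[0].score < 0.60


def test_pure_linker_region_has_no_sensitive_hits(models):
    seq = _linker(200)
    assert scan_sensitive(seq, (0, 200), list(models.values())) == []


def test_degraded_dim_rescued_only_by_sensitive_tier(models):
    """The poorly conserved dimerization domain escapes the stringent
    scan but is recovered by the sensitive pass."""
    dim = models[DIM]
    h1, h2 = dim.sub_motifs
    loop = dim.consensus[len(h1):-len(h2)]
    degraded = _degrade_to_half(h1) + loop + _degrade_to_half(h2)
    seq = _linker(30) + degraded + _linker(30)
    assert scan_standard(seq, [dim]) == []
    hits = scan_two_tier(seq, [dim])
    assert [h.family_name for h in hits] == [DIM]
    assert hits[0].mode == "sensitive"


@pytest.mark.parametrize(
    "gap_len,rescued",
    [(100, True), (110, True), (99, False), (90, False)],
)
def test_rescue_boundary_at_min_uncovered_len(models, gap_len, rescued):
    """A degraded domain is rescued iff its unannotated region reaches
    the 100-residue cutoff (both sides of the boundary)."""
    p2 = models[P2]
    hat = models[HATPASE]
    pad = gap_len - p2.length  # linker completing the uncovered region
    seq = hat.consensus + _linker(pad) + _degrade_to_half(p2.consensus) + hat.consensus
    hits = scan_two_tier(seq, [p2, hat])
    p2_hits = [h for h in hits if h.family_name == P2]
    assert bool(p2_hits) is rescued
    assert len([h for h in hits if h.family_name == HATPASE]) == 2


def test_two_tier_is_superset_of_standard(small_clean_cohort, models):
    cohort = small_clean_cohort
    mlist = list(models.values())
    for row in cohort.truth[:50]:
        seq = cohort.sequences[row.protein_id]
        std = {(h.family_name, h.start, h.end) for h in scan_standard(seq, mlist)}
        two = {(h.family_name, h.start, h.end) for h in scan_two_tier(seq, mlist)}
        assert std <= two
        assert std == two  # no degradation => rescue adds nothing


def test_lowering_sensitive_threshold_never_removes_hits(default_config, models):
    cohort = cs.generate_cohort(default_config.replace(degrade_prob=0.5), 40, seed=13)
    mlist = list(models.values())
    for pid, seq in cohort.sequences.items():
        hi = scan_two_tier(seq, mlist, cs.ScanConfig(sensitive_identity_threshold=0.40))
        lo = scan_two_tier(seq, mlist, cs.ScanConfig(sensitive_identity_threshold=0.30))
        hi_set = {(h.family_name, h.start, h.end) for h in hi}
        lo_set = {(h.family_name, h.start, h.end) for h in lo}
        assert hi_set <= lo_set
        std_hi = {(h.family_name, h.start, h.end) for h in hi if h.mode == "standard"}
        std_lo = {(h.family_name, h.start, h.end) for h in lo if h.mode == "standard"}
        assert std_hi == std_lo  # standard tier invariant to sensitive threshold


def test_hit_invariants_on_default_cohort(default_config, models):
    cohort = cs.generate_cohort(default_config, 60, seed=17)
    cfg = cs.ScanConfig()
    for pid, seq in cohort.sequences.items():
        for h in scan_two_tier(seq, list(models.values()), cfg, protein_id=pid):
            assert 0 <= h.start < h.end <= len(seq)
            if h.mode == "standard":
                assert h.score >= cfg.standard_identity_threshold
            elif h.mode == "sensitive":
                assert h.score >= cfg.sensitive_identity_threshold


# -- uncovered regions -------------------------------------------------------

def _mk(s, e):
    return DomainHit("p", HPT, s, e, 1.0)


def test_uncovered_regions_no_hits():
    assert uncovered_regions([], 250, 100) == [(0, 250)]


def test_uncovered_regions_small_gap_dropped():
    assert uncovered_regions([_mk(0, 100), _mk(150, 250)], 250, 100) == []


def test_uncovered_regions_terminal_gap():
    assert uncovered_regions([_mk(0, 40)], 250, 100) == [(40, 250)]


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(st.integers(0, 480), st.integers(1, 80)), min_size=0, max_size=8
    ),
    st.integers(1, 150),
)
def test_uncovered_regions_matches_mask_oracle(intervals, min_len):
    """Complement-interval oracle: boolean coverage mask at 500 positions."""
    seq_len = 500
    hits = [_mk(s, min(s + l, seq_len)) for s, l in intervals if s < seq_len]
    got = uncovered_regions(hits, seq_len, min_len)
    mask = np.zeros(seq_len, dtype=bool)
    for h in hits:
        mask[h.start:h.end] = True
    expected = []
    i = 0
    while i < seq_len:
        if not mask[i]:
            j = i
            while j < seq_len and not mask[j]:
                j += 1
            if j - i >= min_len:
                expected.append((i, j))
            i = j
        else:
            i += 1
    assert got == expected
    # regions are disjoint from hits and sorted
    for s, e in got:
        assert not mask[s:e].any()
    assert got == sorted(got)


# -- hit table I/O -----------------------------------------------------------

def test_hits_table_round_trip(tmp_path):
    hits = [
        DomainHit("p1", HPT, 4, 94, 0.9876, "standard"),
        DomainHit("p1", CHEW, 120, 170, 0.5, "sensitive", partial=True),
        DomainHit("p2", HATPASE, 0, 110, 1.0, "ingested", merged_from=2),
    ]
    path = tmp_path / "hits.tsv"
    cio.write_hits_table(hits, path)
    back = cio.read_hits_table(path)
    assert [
        (h.protein_id, h.family_name, h.start, h.end, h.mode, h.partial, h.merged_from)
        for h in back
    ] == [
        (h.protein_id, h.family_name, h.start, h.end, h.mode, h.partial, h.merged_from)
        for h in hits
    ]
    assert all(abs(a.score - b.score) < 1e-4 for a, b in zip(hits, back))


def test_hits_table_end_before_start_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "protein_id\tfamily\tstart_1based\tend_1based\tscore\tmode\tpartial\tmerged_from\n"
        "p1\tHpt\t50\t10\t0.9\tstandard\t0\t1\n"
    )
    with pytest.raises(cio.ParseError, match="line 2"):
        cio.read_hits_table(path)


def test_hits_table_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("protein_id\tfamily\n" "p1\tHpt\n")
    with pytest.raises(cio.ParseError, match="missing columns"):
        cio.read_hits_table(path)


def test_domtblout_env_coordinates_become_half_open(tmp_path):
    """domtblout row with env 5..64 ingests as internal (4, 64)."""
    # minimal hmmsearch --domtblout layout (23 columns), one domain row
    row = (
        "prot1 - 400 Hpt PF01627.1 90 1e-40 120.0 0.1 1 1 "
        "1e-42 1e-41 118.0 0.1 1 90 5 64 5 64 0.95 -"
    )
    header = "#" + " " * 20 + "\n"
    path = tmp_path / "hits.domtblout"
    path.write_text(header + " ".join(row.split()) + "\n")
    hits = cio.read_domtblout(path)
    assert len(hits) == 1
    h = hits[0]
    assert (h.protein_id, h.family_name, h.start, h.end, h.mode) == (
        "prot1", "Hpt", 4, 64, "ingested"
    )
    assert h.score == pytest.approx(0.95)
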