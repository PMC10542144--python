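"""Residue-level domain features.

Conserved-histidine calls for Hpt copies: the hit sequence is globally
aligned to the family consensus (match +1, mismatch -1, gap open -2, gap
extend -1) and the residue sitting in the consensus phosphorylation-site
column — position 48 of the reference kinase numbering — is inspected,
with a one-column tolerance on either side to absorb local alignment
ambiguity.  Partial-domain flagging marks hits covering less than a
configurable fraction of their model's minimum length (degenerate copies
such as a kinase domain missing a full helix).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from .config import ScanConfig
from .models import HPT, DomainModel, default_models
from .scan import DomainHit


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise FeatureError("gap penalties must be negative")
        if self.match <= self.mismatch:
            raise FeatureError("match score must exceed mismatch score")

    def aligner(self) -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass(frozen=True)
class HptSiteCall:
    protein_id: str
    hpt_index: int  # ordinal of the Hpt copy, N->C, starting at 1
    his_present: bool
    aligned_position: int | None  # 0-based offset within the hit, or None


def check_conserved_his(
    hit_seq: str,
    model: DomainModel | None = None,
    params: AlignmentParams | None = None,
    protein_id: str = "query",
    hpt_index: int = 1,
) -> HptSiteCall:
    """Call conserved-His presence in one Hpt hit sequence."""
    model = model or default_models()[HPT]
    params = params or AlignmentParams()
    if model.conserved_site_offset is None or model.conserved_site_residue != "H":
        raise FeatureError(f"model {model.family_name} carries no conserved-His annotation")
    if len(hit_seq) < 10:
        raise FeatureError("hit too short for a defined His call (< 10 residues)")

    aln = params.aligner().align(model.consensus, hit_seq)[0]
    target_gapped, query_gapped = str(aln[0]), str(aln[1])
    site = model.conserved_site_offset

    # locate the alignment column holding consensus position `site`
    col_of_site = None
    t_pos = 0
    for col, ch in enumerate(target_gapped):
        if ch != "-":
            if t_pos == site:
                col_of_site = col
                break
            t_pos += 1
    if col_of_site is None:  # site fell off the alignment entirely
        return HptSiteCall(protein_id, hpt_index, False, None)

    his_present = False
    aligned_position = None
    for col in (col_of_site, col_of_site - 1, col_of_site + 1):
        if not 0 <= col < len(query_gapped):
            continue
        if query_gapped[col] == "-":
            continue
        q_pos = sum(1 for c in query_gapped[:col] if c != "-")
        if col == col_of_site:
            aligned_position = q_pos
        if query_gapped[col] == "H":
            his_present = True
            if aligned_position is None:
                aligned_position = q_pos
            break
    return HptSiteCall(protein_id, hpt_index, his_present, aligned_position)


def call_hpt_sites(
    seq: str,
    hits: list[DomainHit],
    model: DomainModel | None = None,
    params: AlignmentParams | None = None,
) -> list[HptSiteCall]:
    """His calls for every Hpt hit of one protein, N->C order."""
    model = model or default_models()[HPT]
    hpt_hits = sorted((h for h in hits if h.family_name == HPT), key=lambda h: h.start)
    calls = []
    for i, h in enumerate(hpt_hits, start=1):
        calls.append(
            check_conserved_his(seq[h.start:h.end], model, params, h.protein_id, i)
        )
    return calls


def flag_partial(hit: DomainHit, model: DomainModel, cfg: ScanConfig | None = None) -> bool:
    """True iff the hit covers less than the partial-coverage fraction of
    the model's minimum length (strict inequality at the boundary)."""
    cfg = cfg or ScanConfig()
    return (hit.end - hit.start) < cfg.min_model_coverage_partial * model.min_len
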