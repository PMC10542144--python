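"""From hit lists to clean ordered domain architectures.

Three steps: greedy overlap resolution (highest score wins), split-hit
merging (consecutive same-family fragments separated by at most
``max_merge_gap`` residues collapse into one domain, provided the merged
span stays within the family's plausible length and no other family's hit
intervenes), and flag computation.  Merging is what corrects the
two-hits-for-one-CheW artefact caused by mid-domain insertions while
leaving genuine CheW duplications — whose merged span would exceed any
single CheW — untouched, and never bridges across an intervening domain
(preserving true CheW–CheY-like–CheW arrangements).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import BuilderConfig
from .models import CHEC_LIKE, CHEW, CHEY_LIKE, DIM, HATPASE, HPT, P2
from .scan import DomainHit

#: Families considered "core-like" for positional rules (everything that
#: is not an auxiliary receiver/phosphatase domain).
_POSITIONAL_CORE = (HPT, P2, DIM, HATPASE, CHEW)


@dataclass
class ArchitectureRecord:
    """Per-protein ordered architecture with classification flags."""

    protein_id: str
    class_label: str
    domains: list[DomainHit]
    arch_string: str
    copy_counts: dict[str, int]
    flags: dict[str, bool]

    @property
    def families(self) -> list[str]:
        return [d.family_name for d in self.domains]

    def count(self, family: str) -> int:
        return self.copy_counts.get(family, 0)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy maximum-score disjoint selection.

    Hits are taken in decreasing score (ties: smaller start, then
    lexicographic family name); a hit is kept iff it is disjoint from all
    previously kept hits.  Idempotent.
    """
    order = sorted(hits, key=lambda h: (-h.score, h.start, h.family_name))
    kept: list[DomainHit] = []
    for h in order:
        if all(not h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def merge_split_hits(
    hits: Sequence[DomainHit], cfg: BuilderConfig | None = None
) -> list[DomainHit]:
    """Merge consecutive same-family fragments (see module docstring).

    Requires disjoint, start-sorted hits.  Idempotent: a merged hit's
    span already exceeds ``family_max_len`` minus slack for any further
    legal merge with a genuine neighbouring copy.
    """
    cfg = cfg or BuilderConfig()
    hits = sorted(hits, key=lambda h: h.start)
    changed = True
    while changed:
        changed = False
        out: list[DomainHit] = []
        i = 0
        while i < len(hits):
            cur = hits[i]
            if i + 1 < len(hits):
                nxt = hits[i + 1]
                max_len = cfg.family_max_len.get(cur.family_name, 0)
                if (
                    nxt.family_name == cur.family_name
                    and nxt.start - cur.end <= cfg.max_merge_gap
                    and nxt.end - cur.start <= max_len + cfg.max_merge_gap
                ):
                    total = (cur.end - cur.start) + (nxt.end - nxt.start)
                    score = (
                        cur.score * (cur.end - cur.start) + nxt.score * (nxt.end - nxt.start)
                    ) / total
                    mode = cur.mode if cur.score >= nxt.score else nxt.mode
                    merged = DomainHit(
                        cur.protein_id,
                        cur.family_name,
                        cur.start,
                        nxt.end,
                        score,
                        mode,
                        partial=False,
                        merged_from=cur.merged_from + nxt.merged_from,
                    )
                    out.append(merged)
                    i += 2
                    changed = True
                    continue
            out.append(cur)
            i += 1
        hits = out
    return list(hits)


def build_architecture(
    protein_id: str,
    class_label: str,
    hits: Sequence[DomainHit],
    cfg: BuilderConfig | None = None,
) -> ArchitectureRecord:
    """Assemble the ordered architecture record from merged, disjoint hits."""
    cfg = cfg or BuilderConfig()
    domains = sorted(hits, key=lambda h: h.start)
    families = [d.family_name for d in domains]
    copy_counts: dict[str, int] = {}
    for f in families:
        copy_counts[f] = copy_counts.get(f, 0) + 1
    arch_string = ",".join(families)
    canonical = tuple(families) == tuple(cfg.canonical_architecture)
    is_chea = copy_counts.get(HATPASE, 0) >= 1 and copy_counts.get(CHEW, 0) >= 1
    chey_positions = locate_positions(families)
    flags = {
        "is_cheA": is_chea,
        "canonical_five": canonical,
        "lacks_P2": copy_counts.get(P2, 0) == 0,
        "multi_Hpt": copy_counts.get(HPT, 0) >= 2,
        "two_CheW": copy_counts.get(CHEW, 0) == 2,
        "cheY_like_present": copy_counts.get(CHEY_LIKE, 0) >= 1,
        "cheY_like_N_terminal": "N_terminal" in chey_positions,
        "dim_extended": any(
            d.family_name == DIM and d.length > cfg.classical_dim_max_len for d in domains
        ),
        "has_cheC_fusion": is_chea and copy_counts.get(CHEC_LIKE, 0) >= 1,
        "truncated_candidate": False,
        "bipartite_partner_found": False,
    }
    return ArchitectureRecord(protein_id, class_label, domains, arch_string, copy_counts, flags)


def classify_chea(rec: ArchitectureRecord) -> str:
    """'cheA' iff both universally detectable core domains are present.

    The kinase (HATPase_c) + CheW pair uniquely distinguishes CheA
    homologs; the dimerization domain is expected too but its detection
    is sensitivity-limited, so it is recorded separately rather than
    required for the call.
    """
    return "cheA" if rec.flags["is_cheA"] else "not_cheA"


def locate_positions(families: Sequence[str]) -> set[str]:
    """Positional categories for every CheY-like copy (order-based rule).

    A copy before the first core-like domain is N_terminal; after the
    last CheW, C_terminal; anything else internal.
    """
    core_idx = [i for i, f in enumerate(families) if f in _POSITIONAL_CORE]
    chew_idx = [i for i, f in enumerate(families) if f == CHEW]
    out: set[str] = set()
    for i, f in enumerate(families):
        if f != CHEY_LIKE:
            continue
        if core_idx and i < core_idx[0]:
            out.add("N_terminal")
        elif chew_idx and i > chew_idx[-1]:
            out.add("C_terminal")
        else:
            out.add("internal")
    return out


def locate_cheY_like(rec: ArchitectureRecord) -> set[str] | str:
    """Positions of CheY-like copies; 'absent' when there are none."""
    positions = locate_positions(rec.families)
    return positions if positions else "absent"


def build_records(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    class_by_protein: Mapping[str, str],
    cfg: BuilderConfig | None = None,
) -> list[ArchitectureRecord]:
    """Resolve, merge and build one record per protein (pipeline helper)."""
    cfg = cfg or BuilderConfig()
    records = []
    for pid, hits in hits_by_protein.items():
        clean = merge_split_hits(resolve_overlaps(hits), cfg)
        records.append(
            build_architecture(pid, class_by_protein.get(pid, "unassigned"), clean, cfg)
        )
    return records
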