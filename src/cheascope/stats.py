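"""Dataset-level architecture statistics.

Percentages are held as exact fractions internally and rounded only when
tables are written.  The core-domain determination follows the survey's
argument: a family is core when it is present in every record whose
absence is not independently explained — a gene truncated at a contig
end, or a bipartite system whose Hpt travels as a standalone gene in the
same operon.  Under that rule Hpt joins the kinase, CheW and
dimerization domains in the core set even though its raw presence is
below 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .architecture import ArchitectureRecord
from .models import ALL_FAMILIES


class CohortError(ValueError):
    pass


#: Record flags exposed as summary categories.
CATEGORY_FLAGS = (
    "canonical_five",
    "lacks_P2",
    "multi_Hpt",
    "two_CheW",
    "cheY_like_present",
    "cheY_like_N_terminal",
    "dim_extended",
    "has_cheC_fusion",
)


@dataclass
class CohortSummary:
    n_records: int
    presence_pct: dict[str, float]
    duplication_pct: dict[str, float]
    category_pct: dict[str, float]
    class_profiles: dict[str, tuple[str, float]]
    core_set: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "presence_pct": {k: round(v, 1) for k, v in self.presence_pct.items()},
            "duplication_pct": {k: round(v, 1) for k, v in self.duplication_pct.items()},
            "category_pct": {k: round(v, 1) for k, v in self.category_pct.items()},
            "class_profiles": {
                k: {"arch": a, "pct": round(p, 1)} for k, (a, p) in self.class_profiles.items()
            },
            "core_set": sorted(self.core_set),
        }


def records_frame(records: Sequence[ArchitectureRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per protein)."""
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "class": r.class_label,
            "arch_string": r.arch_string,
        }
        for fam in ALL_FAMILIES:
            row[f"n_{fam}"] = r.count(fam)
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def composition_summary(
    records: Sequence[ArchitectureRecord],
    core: frozenset[str] | None = None,
) -> CohortSummary:
    """Per-family presence/duplication and category percentages."""
    n = len(records)
    if n == 0:
        raise CohortError("cannot summarize an empty cohort")
    df = records_frame(records)
    presence = {f: 100.0 * (df[f"n_{f}"] >= 1).mean() for f in ALL_FAMILIES}
    duplication = {f: 100.0 * (df[f"n_{f}"] > 1).mean() for f in ALL_FAMILIES}
    category = {flag: 100.0 * df[flag].mean() for flag in CATEGORY_FLAGS}
    profiles = class_profiles(records)
    return CohortSummary(n, presence, duplication, category, profiles, core or frozenset())


def co_occurrence(
    records: Sequence[ArchitectureRecord],
    predicate_a: str | Callable[[ArchitectureRecord], bool],
    predicate_b: str | Callable[[ArchitectureRecord], bool],
    class_filter: str | None = None,
) -> tuple[int, int, float]:
    """Conditional percentage of B among records satisfying A.

    Predicates are flag names of :class:`ArchitectureRecord` or callables.
    Raises :class:`CohortError` when no record satisfies A (never a
    silent zero).
    """

    def as_fn(p):
        if callable(p):
            return p
        if isinstance(p, str):
            return lambda r: bool(r.flags[p])
        raise CohortError(f"bad predicate {p!r}")

    fa, fb = as_fn(predicate_a), as_fn(predicate_b)
    pool = [r for r in records if class_filter is None or r.class_label == class_filter]
    n_a = sum(1 for r in pool if fa(r))
    if n_a == 0:
        raise CohortError("conditional undefined: no record satisfies predicate A")
    n_ab = sum(1 for r in pool if fa(r) and fb(r))
    return n_a, n_ab, 100.0 * n_ab / n_a


def class_profiles(
    records: Sequence[ArchitectureRecord],
) -> dict[str, tuple[str, float]]:
    """Per class: the modal architecture string and its share (%).

    Ties broken lexicographically for determinism.
    """
    by_class: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for r in records:
        by_class.setdefault(r.class_label, {})
        by_class[r.class_label][r.arch_string] = by_class[r.class_label].get(r.arch_string, 0) + 1
        totals[r.class_label] = totals.get(r.class_label, 0) + 1
    out = {}
    for cls, counts in by_class.items():
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[cls] = (best[0], 100.0 * best[1] / totals[cls])
    return out


def core_domain_set(records: Sequence[ArchitectureRecord]) -> frozenset[str]:
    """Families present in 100% of records after excluding records whose
    absence is explained (truncated_candidate or bipartite_partner_found).

    A family absent from every record is never core.
    """
    if not records:
        raise CohortError("cannot determine a core set for an empty cohort")
    core = set()
    for fam in ALL_FAMILIES:
        present_somewhere = any(r.count(fam) >= 1 for r in records)
        if not present_somewhere:
            continue
        unexplained_absent = [
            r
            for r in records
            if r.count(fam) == 0
            and not (r.flags.get("truncated_candidate") or r.flags.get("bipartite_partner_found"))
        ]
        if not unexplained_absent:
            core.add(fam)
    return frozenset(core)
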