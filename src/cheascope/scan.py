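"""Two-tier domain detection.

The scanner is a documented stand-in for profile searches: each family is
scored by ungapped windowed identity against its consensus.  The *standard*
tier (threshold 0.60) emulates stringent profile-HMM detection over the
whole sequence; the *sensitive* tier (threshold 0.40) emulates
profile-profile rescue and is applied only to unannotated regions of at
least ``min_uncovered_len`` residues (default 100, the average domain
size), exactly mirroring the survey's two-step procedure.  Real hit tables
(native TSV or HMMER ``--domtblout``) can be ingested instead of scanning.

Fragment awareness: besides the full consensus window, each family's two
consensus halves are scanned as sub-segments.  An intact domain yields one
full-window hit (half matches are suppressed as overlaps); a split domain
— e.g. a CheW interrupted by a mid-domain insertion — yields two fragment
hits, reproducing the two-hits-for-one-domain artefact that stringent
profile searches produce on such proteins.  The dimerization domain is
scanned via its two helix sub-motifs, with a helix-1 match paired to the
nearest downstream helix-2 match within ``dim_pairing_max_span`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import ScanConfig
from .models import DIM, DomainModel, default_models

MODES = ("standard", "sensitive", "ingested")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """One detected domain instance (0-based half-open coordinates)."""

    protein_id: str
    family_name: str
    start: int
    end: int
    score: float
    mode: str = "standard"
    partial: bool = False
    merged_from: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ScanError(f"{self.protein_id}/{self.family_name}: bad interval")
        if self.mode not in MODES:
            raise ScanError(f"bad mode {self.mode!r}")
        if self.merged_from < 1:
            raise ScanError("merged_from must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start < other.end and other.start < self.end


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _window_identity(seq_arr: np.ndarray, cons: np.ndarray) -> np.ndarray:
    """Identity of every length-len(cons) window of seq_arr to cons."""
    L = len(cons)
    if len(seq_arr) < L:
        return np.empty(0, dtype=float)
    win = sliding_window_view(seq_arr, L)
    return (win == cons).mean(axis=1)


def _segment_candidates(
    seq_arr: np.ndarray, cons: str, threshold: float
) -> list[tuple[int, int, float]]:
    cons_arr = _encode(cons)
    ident = _window_identity(seq_arr, cons_arr)
    idx = np.nonzero(ident >= threshold)[0]
    L = len(cons)
    return [(int(i), int(i) + L, float(ident[i])) for i in idx]


def _suppress(cands: list[tuple[int, int, float, int]]) -> list[tuple[int, int, float]]:
    """Greedy same-family suppression.

    Overlapping candidates are ranked by matching-residue count
    (identity x window length) so that a full-window match beats its own
    half-window sub-matches even when a single substitution dents its
    identity, while a genuinely split domain — where the full window
    scores near 50% — still resolves to its two fragments at the
    stringent threshold.  Ties break to smaller start, then longer
    segment, keeping the scan deterministic.
    """
    order = sorted(cands, key=lambda c: (-c[2] * (c[1] - c[0]), c[0], -(c[1] - c[0])))
    kept: list[tuple[int, int, float]] = []
    for s, e, sc, _ in order:
        if all(e <= ks or ke <= s for ks, ke, _ in kept):
            kept.append((s, e, sc))
    kept.sort()
    return kept


def _scan_simple_family(
    seq_arr: np.ndarray,
    model: DomainModel,
    threshold: float,
    min_coverage_partial: float,
) -> list[tuple[int, int, float, bool]]:
    """Candidates for a non-dimerization family: full window plus halves."""
    cons = model.consensus
    h = len(cons) // 2
    cands: list[tuple[int, int, float, int]] = []
    for seg_rank, seg_cons, offset in (
        (0, cons, 0),
        (1, cons[:h], 0),
        (1, cons[h:], 0),
    ):
        for s, e, sc in _segment_candidates(seq_arr, seg_cons, threshold):
            cands.append((s, e, sc, seg_rank))
    kept = _suppress(cands)
    out = []
    for s, e, sc in kept:
        partial = (e - s) < min_coverage_partial * model.min_len
        out.append((s, e, sc, partial))
    return out


def _scan_dim_family(
    seq_arr: np.ndarray,
    model: DomainModel,
    threshold: float,
    cfg: ScanConfig,
) -> list[tuple[int, int, float, bool]]:
    """Pair helix-1 matches with the nearest downstream helix-2 match."""
    h1, h2 = model.sub_motifs  # type: ignore[misc]
    c1 = _suppress([(s, e, sc, 0) for s, e, sc in _segment_candidates(seq_arr, h1, threshold)])
    c2 = _suppress([(s, e, sc, 0) for s, e, sc in _segment_candidates(seq_arr, h2, threshold)])
    out = []
    used: set[int] = set()
    for s1, e1, sc1 in c1:
        best = None
        for j, (s2, e2, sc2) in enumerate(c2):
            if j in used or s2 < e1:
                continue
            if e2 - s1 > cfg.dim_pairing_max_span:
                break
            best = (j, s2, e2, sc2)
            break
        if best is None:
            continue  # unpaired sub-motif matches are discarded
        j, s2, e2, sc2 = best
        used.add(j)
        span = e2 - s1
        score = (sc1 * (e1 - s1) + sc2 * (e2 - s2)) / ((e1 - s1) + (e2 - s2))
        partial = span < cfg.min_model_coverage_partial * model.min_len
        out.append((s1, e2, score, partial))
    return out


def _scan(
    seq: str,
    models: Sequence[DomainModel],
    cfg: ScanConfig,
    threshold: float,
    mode: str,
    protein_id: str,
    offset: int = 0,
) -> list[DomainHit]:
    if not models:
        raise ScanError("models must be non-empty")
    if not seq:
        return []
    seq_arr = _encode(seq)
    hits: list[DomainHit] = []
    for model in models:
        if model.family_name == DIM:
            raw = _scan_dim_family(seq_arr, model, threshold, cfg)
        else:
            raw = _scan_simple_family(seq_arr, model, threshold, cfg.min_model_coverage_partial)
        for s, e, sc, partial in raw:
            hits.append(
                DomainHit(protein_id, model.family_name, s + offset, e + offset, sc, mode, partial)
            )
    hits.sort(key=lambda hit: (hit.start, hit.end, hit.family_name))
    return hits


def scan_standard(
    seq: str,
    models: Sequence[DomainModel] | None = None,
    cfg: ScanConfig | None = None,
    protein_id: str = "query",
) -> list[DomainHit]:
    """Stringent whole-sequence pass (identity >= standard threshold)."""
    cfg = cfg or ScanConfig()
    models = list(models) if models else list(default_models().values())
    return _scan(seq, models, cfg, cfg.standard_identity_threshold, "standard", protein_id)


def uncovered_regions(
    hits: Iterable[DomainHit], seq_len: int, min_len: int
) -> list[tuple[int, int]]:
    """Maximal hit-free intervals of length >= min_len, termini included."""
    intervals = sorted((h.start, h.end) for h in hits)
    out: list[tuple[int, int]] = []
    cursor = 0
    for s, e in intervals:
        if s > cursor and s - cursor >= min_len:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if seq_len - cursor >= min_len:
        out.append((cursor, seq_len))
    return out


def scan_sensitive(
    seq: str,
    region: tuple[int, int],
    models: Sequence[DomainModel] | None = None,
    cfg: ScanConfig | None = None,
    protein_id: str = "query",
) -> list[DomainHit]:
    """Sensitive pass restricted to ``region`` (0-based half-open)."""
    cfg = cfg or ScanConfig()
    models = list(models) if models else list(default_models().values())
    s, e = region
    if not 0 <= s <= e <= len(seq):
        raise ScanError(f"region {region} outside sequence of length {len(seq)}")
    return _scan(
        seq[s:e], models, cfg, cfg.sensitive_identity_threshold, "sensitive", protein_id, offset=s
    )


def scan_two_tier(
    seq: str,
    models: Sequence[DomainModel] | None = None,
    cfg: ScanConfig | None = None,
    protein_id: str = "query",
) -> list[DomainHit]:
    """Standard pass, then sensitive rescue over unannotated regions of at
    least ``min_uncovered_len`` residues.  Every standard hit is retained."""
    cfg = cfg or ScanConfig()
    models = list(models) if models else list(default_models().values())
    hits = scan_standard(seq, models, cfg, protein_id)
    for region in uncovered_regions(hits, len(seq), cfg.min_uncovered_len):
        hits.extend(scan_sensitive(seq, region, models, cfg, protein_id))
    hits.sort(key=lambda hit: (hit.start, hit.end, hit.family_name))
    return hits
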