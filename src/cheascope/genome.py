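"""Genome-context analyses.

Three calls explain or exploit gene neighborhoods: (i) contig-end
truncation flags cheA genes whose coordinates fall within a margin of a
contig boundary (a sequencing/assembly artefact that can clip the
Hpt-encoding 5' region), (ii) bipartite detection pairs an Hpt-less cheA
with a standalone hpt gene in the same operon (and reports two-cheA
operons where one partner lacks Hpt, the split-kinase arrangement), and
(iii) the phosphate-sink test measures how many genomes with a single
CheY-like-bearing CheA lack all dedicated CheY phosphatases (cheZ, cheC,
cheX) — the genomic evidence for the receiver domain's sink role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .architecture import ArchitectureRecord
from .config import GenomeCallConfig
from .synthetic import Gene, GenomeSpec


class GenomeError(ValueError):
    pass


@dataclass
class CheaCall:
    gene_id: str
    protein_id: str
    lacks_Hpt: bool
    truncated_candidate: bool
    bipartite_partner_found: bool


@dataclass
class GenomeCalls:
    genome_id: str
    cheA_count: int
    chea_calls: list[CheaCall]
    has_phosphatase: bool
    sink_eligible: bool  # exactly one cheA AND that cheA bears a CheY-like
    chea_pairs: list[tuple[str, str]] = field(default_factory=list)  # two-cheA operons


def flag_contig_truncation(
    gene: Gene, contig_length: int, cfg: GenomeCallConfig | None = None
) -> bool:
    """True iff the gene starts or ends within the contig-end margin."""
    cfg = cfg or GenomeCallConfig()
    return gene.start < cfg.contig_end_margin or gene.end > contig_length - cfg.contig_end_margin


def detect_bipartite(
    genome: GenomeSpec,
    arch_by_gene: Mapping[str, ArchitectureRecord],
    cfg: GenomeCallConfig | None = None,
) -> GenomeCalls:
    """Per-cheA flags for one genome (see module docstring).

    ``arch_by_gene`` maps cheA gene ids to their architecture records;
    the records' ``truncated_candidate`` / ``bipartite_partner_found``
    flags are updated in place so downstream cohort statistics can use
    them as absence explanations.
    """
    cfg = cfg or GenomeCallConfig()
    chea_genes = [g for g in genome.genes if g.role == "cheA"]
    hpt_operons = {g.operon_id for g in genome.genes if g.role == "hpt_standalone"}
    phosphatase = any(g.role in cfg.phosphatase_roles for g in genome.genes)

    calls: list[CheaCall] = []
    for g in sorted(chea_genes, key=lambda g: (g.contig_id, g.start)):
        rec = arch_by_gene.get(g.gene_id)
        if rec is None:
            raise GenomeError(f"{genome.genome_id}: no architecture for cheA gene {g.gene_id}")
        lacks_hpt = rec.count("Hpt") == 0
        truncated = lacks_hpt and flag_contig_truncation(
            g, genome.contig_lengths[g.contig_id], cfg
        )
        partner = lacks_hpt and not truncated and g.operon_id in hpt_operons
        rec.flags["truncated_candidate"] = truncated
        rec.flags["bipartite_partner_found"] = partner
        calls.append(CheaCall(g.gene_id, g.protein_id or "", lacks_hpt, truncated, partner))

    # split-kinase arrangement: two cheA genes in one operon, one Hpt-less
    pairs = []
    by_operon: dict[str, list[Gene]] = {}
    for g in chea_genes:
        by_operon.setdefault(g.operon_id, []).append(g)
    lacks = {c.gene_id: c.lacks_Hpt for c in calls}
    for members in by_operon.values():
        if len(members) == 2 and any(lacks[g.gene_id] for g in members):
            pairs.append((members[0].gene_id, members[1].gene_id))

    sink = False
    if len(chea_genes) == 1:
        rec = arch_by_gene[chea_genes[0].gene_id]
        sink = bool(rec.flags["cheY_like_present"])
    return GenomeCalls(genome.genome_id, len(chea_genes), calls, phosphatase, sink, pairs)


def call_genomes(
    genomes: Sequence[GenomeSpec],
    arch_by_gene: Mapping[str, ArchitectureRecord],
    cfg: GenomeCallConfig | None = None,
) -> list[GenomeCalls]:
    return [detect_bipartite(g, arch_by_gene, cfg) for g in genomes]


def phosphate_sink_test(genomes: Sequence[GenomeCalls]) -> tuple[int, int, float]:
    """(n_eligible, n_lacking, percentage lacking phosphatases)."""
    eligible = [g for g in genomes if g.sink_eligible]
    if not eligible:
        raise GenomeError("phosphate-sink test undefined: no eligible genome")
    n_lacking = sum(1 for g in eligible if not g.has_phosphatase)
    return len(eligible), n_lacking, 100.0 * n_lacking / len(eligible)
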