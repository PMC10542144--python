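"""End-to-end orchestration: simulate, scan, build, analyze, report.

Every stage writes its table under ``output_dir`` with a fixed filename
(cohort.fasta, truth.tsv, hits.tsv, arch.tsv, hpt_sites.tsv,
genome_table.tsv, genome_calls.tsv, summary.json), so any stage can be
resumed from the intermediates.  All randomness flows from the single
generator seed; identical configuration gives byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as cio
from .architecture import ArchitectureRecord, build_records
from .config import PipelineConfig
from .features import call_hpt_sites
from .genome import GenomeCalls, call_genomes, phosphate_sink_test
from .models import default_models
from .scan import DomainHit, scan_two_tier
from .stats import CohortSummary, co_occurrence, composition_summary, core_domain_set
from .synthetic import Cohort, GenomeSpec, generate_cohort, generate_genome_cohort

log = logging.getLogger("cheascope")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    output_dir: Path
    records: list[ArchitectureRecord]
    summary: CohortSummary
    report: dict
    genome_calls: list[GenomeCalls] = field(default_factory=list)


def _setup_logging(level: str) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(levelname)s %(name)s] %(message)s"))
        log.addHandler(handler)
    log.setLevel(level.upper())


def scan_cohort(
    sequences: Mapping[str, str], scan_cfg, models=None
) -> dict[str, list[DomainHit]]:
    """Two-tier scan of every protein; returns hits keyed by protein id."""
    models = models or list(default_models().values())
    out: dict[str, list[DomainHit]] = {}
    for pid, seq in sequences.items():
        out[pid] = scan_two_tier(seq, models, scan_cfg, protein_id=pid)
    return out


def analyze_cohort(
    sequences: Mapping[str, str],
    class_by_protein: Mapping[str, str],
    scan_cfg,
    builder_cfg,
) -> tuple[dict[str, list[DomainHit]], list[ArchitectureRecord]]:
    """Scan + architecture building (the library-level workhorse)."""
    hits = scan_cohort(sequences, scan_cfg)
    records = build_records(hits, class_by_protein, builder_cfg)
    return hits, records


def run_pipeline(cfg: PipelineConfig, mode: str = "simulate+analyze",
                 fasta: str | None = None, hits_table: str | None = None,
                 truth_table: str | None = None) -> PipelineResult:
    """Run the full pipeline.

    ``simulate+analyze`` generates a cohort (and a genome cohort when
    ``n_genomes`` > 0) before analysis; ``analyze-only`` expects a FASTA
    file and/or a pre-computed hit table.
    """
    _setup_logging(cfg.log_level)
    if mode not in ("simulate+analyze", "analyze-only"):
        raise PipelineError(f"unknown mode {mode!r}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = default_models()

    genomes: list[GenomeSpec] = []
    sequences: Mapping[str, str] = {}
    class_by_protein: dict[str, str] = {}
    hits_by_protein: dict[str, list[DomainHit]] | None = None
    gene_by_protein: dict[str, str] = {}

    try:
        if mode == "simulate+analyze":
            log.info("simulate: generating %d proteins (seed %d)", cfg.n_proteins, cfg.generator.seed)
            cohort = generate_cohort(cfg.generator, cfg.n_proteins)
            if cfg.n_genomes > 0:
                log.info("simulate: generating %d genomes", cfg.n_genomes)
                genomes, gcohort = generate_genome_cohort(cfg.generator, cfg.n_genomes)
                cohort = Cohort(
                    {**cohort.sequences, **gcohort.sequences}, cohort.truth + gcohort.truth
                )
                cio.write_genome_table(genomes, out / "genome_table.tsv")
            cio.write_cohort(cohort, out / "cohort.fasta", out / "truth.tsv")
            sequences = cohort.sequences
            class_by_protein = {r.protein_id: r.class_label for r in cohort.truth}
        else:
            if fasta is None and hits_table is None:
                raise PipelineError("analyze-only requires a FASTA file or a hit table")
            if fasta is not None:
                sequences = cio.read_fasta(fasta)
            if truth_table is not None:
                class_by_protein = {
                    r.protein_id: r.class_label for r in cio.read_truth_table(truth_table)
                }
            if hits_table is not None:
                loaded = cio.read_hits_table(hits_table)
                hits_by_protein = {}
                for h in loaded:
                    hits_by_protein.setdefault(h.protein_id, []).append(h)

        if hits_by_protein is None:
            log.info("scan: two-tier scan of %d proteins", len(sequences))
            hits_by_protein = scan_cohort(sequences, cfg.scan, list(models.values()))
        all_hits = [h for hs in hits_by_protein.values() for h in hs]
        cio.write_hits_table(all_hits, out / "hits.tsv")

        log.info("architect: building %d records", len(hits_by_protein))
        records = build_records(hits_by_protein, class_by_protein, cfg.builder)
        rec_by_pid = {r.protein_id: r for r in records}

        if sequences:
            log.info("features: conserved-His calls")
            site_rows = []
            for pid, hits in hits_by_protein.items():
                if pid not in sequences:
                    continue
                merged = rec_by_pid[pid].domains
                for call in call_hpt_sites(sequences[pid], merged, models["Hpt"]):
                    site_rows.append(
                        {
                            "protein_id": call.protein_id,
                            "hpt_index": call.hpt_index,
                            "his_present": int(call.his_present),
                            "aligned_position": ""
                            if call.aligned_position is None
                            else call.aligned_position,
                        }
                    )
            pd.DataFrame(
                site_rows, columns=["protein_id", "hpt_index", "his_present", "aligned_position"]
            ).to_csv(out / "hpt_sites.tsv", sep="\t", index=False)
        else:
            log.info("features: no sequences available, His calls skipped")

        genome_calls: list[GenomeCalls] = []
        sink_result = None
        if genomes:
            log.info("genome: context calls for %d genomes", len(genomes))
            arch_by_gene = {}
            for g in genomes:
                for gene in g.genes:
                    if gene.role == "cheA" and gene.protein_id in rec_by_pid:
                        arch_by_gene[gene.gene_id] = rec_by_pid[gene.protein_id]
            genome_calls = call_genomes(genomes, arch_by_gene, cfg.genome)
            rows = [
                {
                    "genome_id": c.genome_id,
                    "cheA_count": c.cheA_count,
                    "has_phosphatase": int(c.has_phosphatase),
                    "sink_eligible": int(c.sink_eligible),
                    "n_truncated": sum(x.truncated_candidate for x in c.chea_calls),
                    "n_bipartite": sum(x.bipartite_partner_found for x in c.chea_calls),
                }
                for c in genome_calls
            ]
            pd.DataFrame(rows).to_csv(out / "genome_calls.tsv", sep="\t", index=False)
            if any(c.sink_eligible for c in genome_calls):
                sink_result = phosphate_sink_test(genome_calls)

        log.info("stats: cohort summary over %d records", len(records))
        chea_records = [r for r in records if r.flags["is_cheA"]]
        core = core_domain_set(chea_records) if chea_records else frozenset()
        summary = composition_summary(chea_records, core)
        cio.write_arch_table(records, out / "arch.tsv")

        report = {"summary": summary.to_dict()}
        try:
            n_a, n_ab, pct = co_occurrence(chea_records, "multi_Hpt", "cheY_like_present")
            report["multi_hpt_with_chey_pct"] = round(pct, 1)
        except Exception:
            pass
        if sink_result is not None:
            n_eligible, n_lacking, pct = sink_result
            report["phosphate_sink"] = {
                "n_eligible": n_eligible,
                "n_lacking": n_lacking,
                "lacking_pct": round(pct, 1),
            }
        cio.write_json(report, out / "summary.json")
        log.info("report: written to %s", out / "summary.json")
        return PipelineResult(out, records, summary, report, genome_calls)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline failed: {exc}") from exc
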