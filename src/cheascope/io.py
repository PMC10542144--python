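"""Readers and writers for the pipeline's file formats.

Coordinates are 0-based half-open in memory and 1-based inclusive in all
emitted tables, following common hit-table conventions.  FASTA goes
through Biopython; tables are tab-separated with fixed headers; HMMER
``--domtblout`` files are ingested via ``Bio.SearchIO`` with envelope
coordinates and the per-domain accuracy column as the score.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architecture import ArchitectureRecord
from .scan import DomainHit
from .stats import records_frame
from .synthetic import Cohort, Gene, GenomeSpec, GroundTruthRow, TrueDomain


class ParseError(ValueError):
    pass


HITS_COLUMNS = [
    "protein_id",
    "family",
    "start_1based",
    "end_1based",
    "score",
    "mode",
    "partial",
    "merged_from",
]

TRUTH_COLUMNS = [
    "protein_id",
    "class",
    "family",
    "start_1based",
    "end_1based",
    "degraded",
    "his_present",
    "split",
    "hpt_mode",
    "genome_id",
]

GENOME_COLUMNS = [
    "genome_id",
    "contig_id",
    "contig_length",
    "gene_id",
    "role",
    "start_1based",
    "end_1based",
    "strand",
    "operon_id",
    "protein_id",
]


# -- FASTA -------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# -- hit tables --------------------------------------------------------------

def write_hits_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "family": h.family_name,
            "start_1based": h.start + 1,
            "end_1based": h.end,
            "score": f"{h.score:.4f}",
            "mode": h.mode,
            "partial": int(h.partial),
            "merged_from": h.merged_from,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_table(path: str | Path) -> list[DomainHit]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse hit table {path}: {exc}") from exc
    missing = set(HITS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"hit table {path} missing columns: {sorted(missing)}")
    hits = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            start = int(row["start_1based"]) - 1
            end = int(row["end_1based"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {line_no}: non-integer coordinates") from exc
        if end <= start:
            raise ParseError(f"{path} line {line_no}: end < start")
        hits.append(
            DomainHit(
                protein_id=str(row["protein_id"]),
                family_name=str(row["family"]),
                start=start,
                end=end,
                score=float(row["score"]),
                mode=str(row["mode"]),
                partial=bool(int(row["partial"])),
                merged_from=int(row["merged_from"]),
            )
        )
    return hits


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Ingest an HMMER3 ``--domtblout`` table (hmmsearch orientation:
    query = profile/family, hit = protein).  Envelope coordinates are
    used; the per-domain expected-accuracy column serves as the score."""
    hits = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    start, end = hsp.env_start, hsp.env_end
                    if end <= start:
                        raise ParseError(f"{path}: end <= start for {hit.id}")
                    hits.append(
                        DomainHit(
                            protein_id=hit.id,
                            family_name=qresult.id,
                            start=start,
                            end=end,
                            score=float(hsp.acc_avg),
                            mode="ingested",
                        )
                    )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse domtblout {path}: {exc}") from exc
    return hits


# -- ground truth ------------------------------------------------------------

def write_truth_table(truth: Sequence[GroundTruthRow], path: str | Path) -> None:
    rows = []
    for r in truth:
        for d in r.true_domains:
            rows.append(
                {
                    "protein_id": r.protein_id,
                    "class": r.class_label,
                    "family": d.family,
                    "start_1based": d.start + 1,
                    "end_1based": d.end,
                    "degraded": int(d.degraded),
                    "his_present": "" if d.his_present is None else int(d.his_present),
                    "split": int(d.split),
                    "hpt_mode": r.hpt_mode,
                    "genome_id": r.genome_id or "",
                }
            )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[GroundTruthRow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, GroundTruthRow] = {}
    for _, row in df.iterrows():
        pid = str(row["protein_id"])
        if pid not in out:
            out[pid] = GroundTruthRow(
                pid,
                str(row["class"]),
                [],
                hpt_mode=str(row["hpt_mode"]),
                genome_id=str(row["genome_id"]) or None,
            )
        his = row["his_present"]
        out[pid].true_domains.append(
            TrueDomain(
                family=str(row["family"]),
                start=int(row["start_1based"]) - 1,
                end=int(row["end_1based"]),
                degraded=bool(int(row["degraded"])),
                his_present=None if his == "" else bool(int(his)),
                split=bool(int(row["split"])),
            )
        )
    return list(out.values())


def write_cohort(cohort: Cohort, fasta_path: str | Path, truth_path: str | Path) -> None:
    write_fasta(cohort.sequences, fasta_path)
    write_truth_table(cohort.truth, truth_path)


# -- genome tables -----------------------------------------------------------

def write_genome_table(genomes: Sequence[GenomeSpec], path: str | Path) -> None:
    rows = []
    for g in genomes:
        for gene in g.genes:
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "contig_id": gene.contig_id,
                    "contig_length": g.contig_lengths[gene.contig_id],
                    "gene_id": gene.gene_id,
                    "role": gene.role,
                    "start_1based": gene.start + 1,
                    "end_1based": gene.end,
                    "strand": gene.strand,
                    "operon_id": gene.operon_id,
                    "protein_id": gene.protein_id or "",
                }
            )
    pd.DataFrame(rows, columns=GENOME_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genome_table(path: str | Path) -> list[GenomeSpec]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(GENOME_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"genome table {path} missing columns: {sorted(missing)}")
    genomes: dict[str, GenomeSpec] = {}
    for _, row in df.iterrows():
        gid = str(row["genome_id"])
        if gid not in genomes:
            genomes[gid] = GenomeSpec(gid, [], {})
        spec = genomes[gid]
        spec.contig_lengths[str(row["contig_id"])] = int(row["contig_length"])
        spec.genes.append(
            Gene(
                gene_id=str(row["gene_id"]),
                role=str(row["role"]),
                contig_id=str(row["contig_id"]),
                start=int(row["start_1based"]) - 1,
                end=int(row["end_1based"]),
                strand=str(row["strand"]),
                operon_id=str(row["operon_id"]),
                protein_id=str(row["protein_id"]) or None,
            )
        )
    for spec in genomes.values():
        spec.validate()
    return list(genomes.values())


# -- architecture tables -----------------------------------------------------

def write_arch_table(records: Sequence[ArchitectureRecord], path: str | Path) -> None:
    records_frame(records).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
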