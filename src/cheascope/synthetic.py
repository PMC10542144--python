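"""Synthetic CheA cohort and genome-neighborhood generator.

Cohorts are drawn from class-conditional architecture templates whose
default weights reproduce the survey's printed frequencies (see
:mod:`cheascope.config`).  On top of the template draw, four sequence-level
phenomena are emulated per domain instance, each recorded in the ground
truth:

* *degradation* — substitutions pinning identity to ~50%, below the
  stringent scan threshold but above the sensitive one, so the domain is
  only recoverable by the rescue tier;
* *split insertions* — a foreign low-complexity insert (default 50
  residues) placed mid-CheW, fragmenting the stringent-tier hit;
* *conserved-His loss* — the Hpt phosphorylation-site histidine replaced
  by another residue;
* *dimerization extension* — extra inter-helix residues stretching the
  classical ~60-residue dimerization domain up to 170 residues.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical (config, n, seed) inputs give
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ArchitectureTemplate, GeneratorConfig
from .models import (
    AMINO_ACIDS,
    CHEW,
    CHEY_LIKE,
    DIM,
    HATPASE,
    HPT,
    LINKER_ALPHABET,
    DomainModel,
    default_models,
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_LINKER = np.frombuffer(LINKER_ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class TrueDomain:
    """Ground truth for one realized domain instance (0-based half-open)."""

    family: str
    start: int
    end: int
    degraded: bool = False
    his_present: bool | None = None
    split: bool = False


@dataclass
class GroundTruthRow:
    protein_id: str
    class_label: str
    true_domains: list[TrueDomain]
    hpt_mode: str = "normal"
    genome_id: str | None = None

    def validate(self, seq_len: int) -> None:
        prev_end = 0
        for d in self.true_domains:
            if not 0 <= d.start < d.end <= seq_len:
                raise ValueError(f"{self.protein_id}: interval out of bounds")
            if d.start < prev_end:
                raise ValueError(f"{self.protein_id}: intervals overlap or unsorted")
            prev_end = d.end

    def families(self) -> list[str]:
        return [d.family for d in self.true_domains]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    role: str  # cheA | hpt_standalone | cheZ | cheC | cheX | other
    contig_id: str
    start: int  # 0-based half-open, nucleotides
    end: int
    strand: str
    operon_id: str
    protein_id: str | None = None


@dataclass
class GenomeSpec:
    genome_id: str
    genes: list[Gene]
    contig_lengths: dict[str, int]

    def validate(self) -> None:
        for g in self.genes:
            if g.contig_id not in self.contig_lengths:
                raise ValueError(f"{self.genome_id}: gene on unknown contig {g.contig_id}")
            if not 0 <= g.start < g.end <= self.contig_lengths[g.contig_id]:
                raise ValueError(f"{self.genome_id}: gene {g.gene_id} outside contig")
        by_operon: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_operon.setdefault(g.operon_id, []).append(g)
        for members in by_operon.values():
            if len({(g.contig_id, g.strand) for g in members}) != 1:
                raise ValueError(f"{self.genome_id}: operon members differ in contig/strand")


def _linker(rng: np.random.Generator, lo: int, hi: int) -> np.ndarray:
    n = int(rng.integers(lo, hi + 1))
    return _LINKER[rng.integers(0, len(_LINKER), n)]


def _degrade(arr: np.ndarray, segments: Sequence[tuple[int, int]], rng: np.random.Generator,
             protect: int | None = None) -> None:
    """Substitute every second residue of each segment in place.

    Pins the identity of any window of the segment to ~0.5, strictly
    between the sensitive (0.40) and standard (0.60) thresholds, which a
    purely sequential random-substitution scheme does not guarantee for
    sub-windows.  ``protect`` is an absolute index never substituted
    (the conserved Hpt histidine, whose presence is tracked separately).
    """
    parity = int(rng.integers(0, 2))
    for s, e in segments:
        for i in range(s + parity, e, 2):
            if i == protect:
                continue
            _substitute(arr, i, rng)


def _substitute(arr: np.ndarray, i: int, rng: np.random.Generator,
                forbid: int | None = None) -> None:
    """Replace ``arr[i]`` with a different residue (optionally also != forbid)."""
    old = arr[i]
    while True:
        new = _AA[int(rng.integers(0, 20))]
        if new != old and new != forbid:
            arr[i] = new
            return


def sample_architecture(
    class_label: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> ArchitectureTemplate:
    """Draw a template for ``class_label`` proportional to template weight."""
    templates = cfg.templates_for(class_label)  # raises KeyError on unknown class
    weights = np.array([t.weight for t in templates], dtype=float)
    weights /= weights.sum()
    idx = int(rng.choice(len(templates), p=weights))
    return templates[idx]


def realize_protein(
    tmpl: ArchitectureTemplate,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    models: dict[str, DomainModel] | None = None,
    protein_id: str = "p1",
) -> tuple[str, GroundTruthRow]:
    """Realize a residue sequence and its ground truth from a template."""
    models = models or default_models()
    lo, hi = cfg.linker_len_range
    pieces: list[np.ndarray] = [_linker(rng, lo, hi)]
    pos = len(pieces[0])
    truth: list[TrueDomain] = []

    for family in tmpl.domain_list:
        model = models[family]
        degraded = rng.random() < cfg.degrade_prob
        his_present: bool | None = None
        split = False

        if family == DIM:
            h1, h2 = model.sub_motifs  # type: ignore[misc]
            loop = model.consensus[len(h1): len(model.consensus) - len(h2)]
            extension = 0
            if rng.random() < cfg.dim_extended_prob:
                # total span in (classical, cap]
                max_ext = cfg.dim_extension_max - model.length
                extension = int(rng.integers(11, max_ext + 1))
            arr = np.concatenate(
                [
                    np.frombuffer(h1.encode(), dtype=np.uint8),
                    np.frombuffer(loop.encode(), dtype=np.uint8),
                    _LINKER[rng.integers(0, len(_LINKER), extension)],
                    np.frombuffer(h2.encode(), dtype=np.uint8),
                ]
            )
            if degraded:
                _degrade(
                    arr,
                    [(0, len(h1)), (len(arr) - len(h2), len(arr))],
                    rng,
                )
        else:
            arr = np.frombuffer(model.consensus.encode(), dtype=np.uint8).copy()
            site = model.conserved_site_offset
            if family == HPT:
                his_present = not (rng.random() < cfg.his_loss_prob)
                if not his_present:
                    _substitute(arr, site, rng)
            if degraded:
                # the conserved site is never touched by degradation: His
                # presence is a separate, exactly-tracked channel
                _degrade(arr, [(0, len(arr))], rng, protect=site)
            if family == CHEW and rng.random() < cfg.split_prob:
                split = True
                mid = len(arr) // 2
                insert = _LINKER[rng.integers(0, len(_LINKER), cfg.split_insert_len)]
                arr = np.concatenate([arr[:mid], insert, arr[mid:]])

        truth.append(
            TrueDomain(family, pos, pos + len(arr), degraded, his_present, split)
        )
        pieces.append(arr)
        pos += len(arr)
        link = _linker(rng, lo, hi)
        pieces.append(link)
        pos += len(link)

    seq = np.concatenate(pieces).tobytes().decode()
    row = GroundTruthRow(protein_id, tmpl.class_label, truth, hpt_mode=tmpl.hpt_mode)
    row.validate(len(seq))
    return seq, row


@dataclass
class Cohort:
    """An in-memory cohort: sequences keyed by protein id plus ground truth."""

    sequences: dict[str, str]
    truth: list[GroundTruthRow]


def _forced_max_hpt_template(cfg: GeneratorConfig) -> ArchitectureTemplate:
    return ArchitectureTemplate(
        class_label="Tfp",
        domain_list=tuple([HPT] * cfg.max_hpt_copies + [DIM, HATPASE, CHEW, CHEY_LIKE]),
        weight=1.0,
    )


def generate_cohort(cfg: GeneratorConfig, n: int, seed: int | None = None) -> Cohort:
    """Generate ``n`` proteins; deterministic for identical (cfg, n, seed).

    One Tfp record (the first sampled, if any) is forced to the maximal
    Hpt copy number (default 14), emulating the single extreme multi-Hpt
    protein reported in the survey.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    models = default_models()
    labels = list(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in labels], dtype=float)
    weights /= weights.sum()
    class_draws = rng.choice(len(labels), size=n, p=weights)

    sequences: dict[str, str] = {}
    truth: list[GroundTruthRow] = []
    forced_done = not cfg.force_max_hpt_record
    for i in range(n):
        label = labels[int(class_draws[i])]
        if label == "Tfp" and not forced_done:
            tmpl = _forced_max_hpt_template(cfg)
            forced_done = True
        else:
            tmpl = sample_architecture(label, cfg, rng)
        pid = f"prot{i + 1:06d}"
        seq, row = realize_protein(tmpl, cfg, rng, models, protein_id=pid)
        sequences[pid] = seq
        truth.append(row)
    return Cohort(sequences, truth)


# ---------------------------------------------------------------------------
# Genome cohorts
# ---------------------------------------------------------------------------

_PHOSPHATASE_CHOICES = (("cheZ",), ("cheC", "cheX"))


def generate_genome_cohort(
    cfg: GeneratorConfig, n_genomes: int, seed: int | None = None
) -> tuple[list[GenomeSpec], Cohort]:
    """Generate gene-neighborhood tables plus the matching protein cohort.

    Each genome holds one or more cheA genes drawn from the class
    mixture; bipartite-mode cheA genes get an ``hpt_standalone`` partner
    in the same operon, truncation-mode cheA genes are placed with their
    3' end inside the contig-end margin, and phosphatase genes (cheZ or
    cheC+cheX) are present per the configured probabilities.  Genomes of
    the phosphate-sink kind (probability ``genome.sink_prob``) carry a
    single cheA guaranteed to bear a CheY-like domain.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    gp = cfg.genome
    models = default_models()
    labels = list(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in labels], dtype=float)
    weights /= weights.sum()
    pool = [c for c in gp.sink_class_pool if c in cfg.class_weights]
    if gp.sink_prob > 0 and not pool:
        raise ValueError("sink_prob > 0 but no sink_class_pool class has templates")
    pool_w = np.array([cfg.class_weights[c] for c in pool], dtype=float)
    if pool:
        pool_w /= pool_w.sum()

    genomes: list[GenomeSpec] = []
    sequences: dict[str, str] = {}
    truth: list[GroundTruthRow] = []
    pid_counter = 0

    for gi in range(n_genomes):
        genome_id = f"g{gi + 1:05d}"
        contig_id = f"{genome_id}_c1"
        is_sink = rng.random() < gp.sink_prob
        if is_sink:
            n_chea = 1
            chea_labels = [pool[int(rng.choice(len(pool), p=pool_w))]]
            p_phos = gp.phosphatase_presence_sink
        else:
            n_chea = int(rng.integers(1, 4))
            chea_labels = [labels[int(rng.choice(len(labels), p=weights))] for _ in range(n_chea)]
            p_phos = gp.phosphatase_presence_other
        has_phosphatase = rng.random() < p_phos
        phos_roles = _PHOSPHATASE_CHOICES[int(rng.integers(0, 2))] if has_phosphatase else ()

        # realize cheA proteins
        chea_entries = []  # (protein_id, hpt_mode, aa_len)
        for label in chea_labels:
            tmpl = sample_architecture(label, cfg, rng)
            pid_counter += 1
            pid = f"{genome_id}_p{pid_counter:06d}"
            seq, row = realize_protein(tmpl, cfg, rng, models, protein_id=pid)
            row.genome_id = genome_id
            sequences[pid] = seq
            truth.append(row)
            chea_entries.append((pid, tmpl.hpt_mode, len(seq)))

        n_other = int(rng.poisson(gp.other_genes_mean))
        ig_lo, ig_hi = gp.intergenic_range

        # lay genes sequentially on one contig; truncated cheA genes are
        # re-positioned against the contig end afterwards.
        genes: list[Gene] = []
        cursor = int(rng.integers(200, 2000))
        op_counter = 0
        gene_counter = 0

        def next_ids() -> tuple[str, str]:
            nonlocal op_counter, gene_counter
            op_counter += 1
            gene_counter += 1
            return f"{genome_id}_gene{gene_counter:04d}", f"{genome_id}_op{op_counter:03d}"

        truncated_entries = []
        for pid, hpt_mode, aa_len in chea_entries:
            gene_id, operon_id = next_ids()
            glen = 3 * aa_len
            if hpt_mode == "truncated":
                truncated_entries.append((gene_id, operon_id, glen, pid))
                continue
            genes.append(Gene(gene_id, "cheA", contig_id, cursor, cursor + glen, "+", operon_id, pid))
            cursor += glen
            if hpt_mode == "bipartite":
                gene_counter += 1
                hpt_len = 3 * models[HPT].length
                gap = int(rng.integers(10, 40))  # tight operonic spacing
                genes.append(
                    Gene(
                        f"{genome_id}_gene{gene_counter:04d}",
                        "hpt_standalone",
                        contig_id,
                        cursor + gap,
                        cursor + gap + hpt_len,
                        "+",
                        operon_id,
                        None,
                    )
                )
                cursor += gap + hpt_len
            cursor += int(rng.integers(ig_lo, ig_hi + 1))

        for role in phos_roles:
            gene_id, operon_id = next_ids()
            glen = int(rng.integers(400, 800))
            genes.append(Gene(gene_id, role, contig_id, cursor, cursor + glen, "+", operon_id, None))
            cursor += glen + int(rng.integers(ig_lo, ig_hi + 1))
        for _ in range(n_other):
            gene_id, operon_id = next_ids()
            glen = int(rng.integers(300, 2000))
            genes.append(Gene(gene_id, "other", contig_id, cursor, cursor + glen, "+", operon_id, None))
            cursor += glen + int(rng.integers(ig_lo, ig_hi + 1))

        clo, chi = gp.contig_length_range
        contig_len = max(cursor + int(rng.integers(500, 3000)), clo)
        contig_len = min(max(contig_len, cursor + 1), max(chi, cursor + 1))
        # truncated cheA genes end within the contig-end margin
        for gene_id, operon_id, glen, pid in truncated_entries:
            offset = int(rng.integers(0, max(1, cfg.genome.contig_end_margin)))
            end = contig_len - offset
            genes.append(Gene(gene_id, "cheA", contig_id, max(0, end - glen), end, "+", operon_id, pid))
        genes.sort(key=lambda g: g.start)

        spec = GenomeSpec(genome_id, genes, {contig_id: contig_len})
        spec.validate()
        genomes.append(spec)

    return genomes, Cohort(sequences, truth)
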