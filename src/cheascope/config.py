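"""Configuration objects for the generator, scanner, builder and genome calls.

The bundled default configuration (``data/default_config.json``) encodes the
survey's reported cohort-level frequencies directly as architecture-template
weights, so that a synthetic cohort drawn from it has, in expectation:

* classical five-domain share 46%
* P2/CheY-binding absent 52%
* Hpt present 98.3% (absence split between contig-truncation 0.9% and
  bipartite operon partners 0.8%)
* exactly two CheW domains 8% (almost all in class F5; 99% of F5 records)
* two or more Hpt copies 18% (ACF 12% + Tfp 4.74% + F4 1.26%, i.e. 93% of
  multi-Hpt records fall in ACF/Tfp and all F4 records carry three Hpt)
* CheY-like present 34%, with P(CheY-like | multi-Hpt, Tfp) = 94%

Configuration files are JSON (YAML is accepted too since JSON is a subset);
:func:`load_paper_parameters` validates every probability and weight sum and
raises :class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

from .models import (
    ALL_FAMILIES,
    CANONICAL_ARCHITECTURE,
    CHEC_LIKE,
    CHEW,
    CHEY_LIKE,
    CLASSICAL_DIM_MAX_LEN,
    DIM,
    DIM_EXTENSION_CAP,
    HATPASE,
    HPT,
    P2,
    default_models,
)


class ConfigError(ValueError):
    """A configuration file or object violates the schema."""


FLAGELLAR_CLASSES = tuple(f"F{i}" for i in range(1, 18))
ALL_CLASSES = FLAGELLAR_CLASSES + ("Tfp", "ACF")

HPT_MODES = ("normal", "truncated", "bipartite")


@dataclass(frozen=True)
class ArchitectureTemplate:
    """One class-conditional architecture with its sampling weight.

    ``weight`` is the probability of the template *within its class*;
    weights of all templates sharing a ``class_label`` sum to one.
    ``hpt_mode`` tags Hpt-less templates with the reason for the absence
    (gene truncated at a contig end, or a bipartite system whose Hpt is a
    standalone gene in the same operon).
    """

    class_label: str
    domain_list: tuple[str, ...]
    weight: float
    hpt_mode: str = "normal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigError(
                f"template weight for class {self.class_label!r} out of [0,1]: {self.weight}"
            )
        unknown = set(self.domain_list) - set(ALL_FAMILIES)
        if unknown:
            raise ConfigError(f"template for {self.class_label!r}: unknown families {unknown}")
        if HATPASE not in self.domain_list or CHEW not in self.domain_list:
            raise ConfigError(
                f"template for {self.class_label!r} must contain HATPase_c and CheW"
            )
        if self.hpt_mode not in HPT_MODES:
            raise ConfigError(f"bad hpt_mode {self.hpt_mode!r}")
        if self.hpt_mode != "normal" and HPT in self.domain_list:
            raise ConfigError(
                f"template for {self.class_label!r}: hpt_mode {self.hpt_mode!r} "
                "but domain_list contains Hpt"
            )


@dataclass(frozen=True)
class GenomeParams:
    """Controls for the genome-neighborhood generator.

    ``sink_prob`` is the probability that a genome is of the
    single-CheA-with-CheY-like kind used by the phosphate-sink test;
    such genomes carry a phosphatase gene (cheZ, or cheC+cheX) with
    probability ``phosphatase_presence_sink`` (default 60/871, the
    survey's reported proportion of sink-eligible genomes that do have a
    phosphatase).  Remaining genomes draw 1–3 CheA genes from the full
    class mixture and carry phosphatases at ``phosphatase_presence_other``.
    """

    sink_prob: float = 0.25
    sink_class_pool: tuple[str, ...] = ("F3", "F5", "ACF")
    phosphatase_presence_sink: float = 60.0 / 871.0
    phosphatase_presence_other: float = 0.85
    other_genes_mean: float = 5.0
    contig_length_range: tuple[int, int] = (20_000, 80_000)
    contig_end_margin: int = 100
    intergenic_range: tuple[int, int] = (50, 300)

    def __post_init__(self) -> None:
        for key in ("sink_prob", "phosphatase_presence_sink", "phosphatase_presence_other"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"genome.{key} out of [0,1]: {v}")
        if self.contig_end_margin < 0:
            raise ConfigError("genome.contig_end_margin must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Validated generator parameters (see module docstring for defaults)."""

    templates: tuple[ArchitectureTemplate, ...]
    class_weights: Mapping[str, float]
    degrade_prob: float = 0.05
    split_prob: float = 0.05
    split_insert_len: int = 50
    his_loss_prob: float = 0.10
    dim_extended_prob: float = 0.20
    dim_extension_max: int = DIM_EXTENSION_CAP
    linker_len_range: tuple[int, int] = (20, 40)
    seed: int = 20230920
    force_max_hpt_record: bool = True
    max_hpt_copies: int = 14
    genome: GenomeParams = field(default_factory=GenomeParams)

    def __post_init__(self) -> None:
        for key in ("degrade_prob", "split_prob", "his_loss_prob", "dim_extended_prob"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} out of [0,1]: {v}")
        if self.split_insert_len < 1:
            raise ConfigError("split_insert_len must be >= 1")
        models = default_models()
        if self.dim_extension_max < models[DIM].min_len:
            raise ConfigError("dim_extension_max below the classical dimerization length")
        lo, hi = self.linker_len_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"linker_len_range invalid: {self.linker_len_range}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        total = math.fsum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_weights sum to {total}, expected 1")
        by_class: dict[str, float] = {}
        for tmpl in self.templates:
            by_class[tmpl.class_label] = by_class.get(tmpl.class_label, 0.0) + tmpl.weight
        for label, s in by_class.items():
            if label not in self.class_weights:
                raise ConfigError(f"templates reference class {label!r} missing from class_weights")
            if abs(s - 1.0) > 1e-9:
                raise ConfigError(f"template weights for class {label!r} sum to {s}, expected 1")
        for label, w in self.class_weights.items():
            if w > 0 and label not in by_class:
                raise ConfigError(f"class_weights[{label!r}] > 0 but no templates given")

    def templates_for(self, class_label: str) -> tuple[ArchitectureTemplate, ...]:
        out = tuple(t for t in self.templates if t.class_label == class_label)
        if not out:
            raise KeyError(f"no templates for class {class_label!r}")
        return out

    def marginal(self, predicate) -> float:
        """Cohort-level probability of ``predicate(template)`` being true."""
        return math.fsum(
            self.class_weights[t.class_label] * t.weight
            for t in self.templates
            if predicate(t)
        )

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ScanConfig:
    """Two-tier scan thresholds.

    ``standard_identity_threshold`` is the stringent whole-sequence pass
    (the profile-HMM stand-in); ``sensitive_identity_threshold`` the
    rescue pass applied to unannotated regions of at least
    ``min_uncovered_len`` residues (the stand-in for profile-profile
    matches at >90% probability).
    """

    standard_identity_threshold: float = 0.60
    sensitive_identity_threshold: float = 0.40
    min_uncovered_len: int = 100
    dim_pairing_max_span: int = DIM_EXTENSION_CAP
    min_model_coverage_partial: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.sensitive_identity_threshold < self.standard_identity_threshold <= 1:
            raise ConfigError(
                "need 0 < sensitive_identity_threshold < standard_identity_threshold <= 1, got "
                f"{self.sensitive_identity_threshold} / {self.standard_identity_threshold}"
            )
        if self.min_uncovered_len < 1:
            raise ConfigError("min_uncovered_len must be >= 1")


@dataclass(frozen=True)
class BuilderConfig:
    """Architecture-construction parameters.

    ``max_merge_gap`` (default 60) accommodates the documented 50-residue
    split-domain insertion with margin; genuine tandem duplications are
    protected by the combined-length guard (merged span must not exceed
    the family's max_len + max_merge_gap), not by the gap alone.
    """

    max_merge_gap: int = 60
    classical_dim_max_len: int = CLASSICAL_DIM_MAX_LEN
    canonical_architecture: tuple[str, ...] = CANONICAL_ARCHITECTURE
    family_max_len: Mapping[str, int] = field(
        default_factory=lambda: {f: m.max_len for f, m in default_models().items()}
    )

    def __post_init__(self) -> None:
        if self.max_merge_gap < 0:
            raise ConfigError("max_merge_gap must be >= 0")


@dataclass(frozen=True)
class GenomeCallConfig:
    """Genome-context call parameters; the contig-end margin is in
    nucleotides and is a configuration choice (no cutoff is dictated by
    the underlying observations)."""

    contig_end_margin: int = 100
    bipartite_scope: str = "same_operon"
    phosphatase_roles: tuple[str, ...] = ("cheZ", "cheC", "cheX")

    def __post_init__(self) -> None:
        if self.contig_end_margin < 0:
            raise ConfigError("contig_end_margin must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig
    scan: ScanConfig = field(default_factory=ScanConfig)
    builder: BuilderConfig = field(default_factory=BuilderConfig)
    genome: GenomeCallConfig = field(default_factory=GenomeCallConfig)
    n_proteins: int = 20_000
    n_genomes: int = 0
    output_dir: str = "cheascope_out"
    log_level: str = "INFO"


# ---------------------------------------------------------------------------
# Default (paper-parameterized) configuration
# ---------------------------------------------------------------------------

#: Hpt copy-number distribution shared by Tfp and ACF multi-Hpt templates;
#: >50% of multi-Hpt records carry five or more copies.
_MULTI_HPT_COPIES = ((2, 0.12), (3, 0.12), (4, 0.16), (5, 0.20), (6, 0.16), (7, 0.14), (8, 0.10))


def _multi_hpt_domains(k: int, chey: int = 1) -> list[str]:
    return [HPT] * k + [DIM, HATPASE, CHEW] + [CHEY_LIKE] * chey


def build_default_config_dict() -> dict[str, Any]:
    """Construct the bundled default configuration as a plain dict.

    Template weights are stored *conditional on class*; joint (cohort)
    weights are the product with the class weight.  The joint-weight
    budget is documented inline; totals reproduce the survey's printed
    marginals exactly (see module docstring).
    """
    classical = list(CANONICAL_ARCHITECTURE)
    four_dom = [HPT, DIM, HATPASE, CHEW]
    core_three = [DIM, HATPASE, CHEW]

    # class -> list of (joint weight, domains, hpt_mode)
    joint: dict[str, list[tuple[float, list[str], str]]] = {
        "F1": [
            (0.30, classical, "normal"),
            (0.10476, four_dom, "normal"),
            (0.002, four_dom + [CHEC_LIKE], "normal"),
            (0.0008, [HPT, DIM, HATPASE, CHEW, CHEW], "normal"),
        ],
        "F2": [
            (0.06, classical, "normal"),
            (0.03, four_dom, "normal"),
            (0.009, core_three, "truncated"),
            (0.008, core_three, "bipartite"),
        ],
        "F3": [
            (0.07144, four_dom + [CHEY_LIKE], "normal"),
            (0.004, [CHEY_LIKE] + four_dom, "normal"),
            (0.02, classical + [CHEY_LIKE], "normal"),
        ],
        "F4": [(0.0126, _multi_hpt_domains(3, chey=0), "normal")],
        "F5": [
            (0.0792, [HPT, DIM, HATPASE, CHEW, CHEW, CHEY_LIKE], "normal"),
            (0.0008, four_dom + [CHEY_LIKE], "normal"),
        ],
        "F6": [(0.02, classical, "normal"), (0.01, four_dom, "normal")],
        "F7": [(0.02, classical, "normal"), (0.02, four_dom, "normal")],
    }
    for label in FLAGELLAR_CLASSES[7:]:  # F8..F17
        joint[label] = [(0.006, classical, "normal")]
    joint["Tfp"] = []
    for k, p in _MULTI_HPT_COPIES:
        joint["Tfp"].append((0.0474 * p * 0.94, _multi_hpt_domains(k, chey=1), "normal"))
        joint["Tfp"].append((0.0474 * p * 0.06, _multi_hpt_domains(k, chey=0), "normal"))
    joint["ACF"] = []
    for k, p in _MULTI_HPT_COPIES:
        w = 0.12 * p
        if k == 3:
            # carve out a duplicated-CheY-like variant
            joint["ACF"].append((w - 0.01, _multi_hpt_domains(3, chey=1), "normal"))
            joint["ACF"].append((0.01, _multi_hpt_domains(3, chey=2), "normal"))
        else:
            joint["ACF"].append((w, _multi_hpt_domains(k, chey=1), "normal"))

    classes = []
    for label, rows in joint.items():
        cw = math.fsum(w for w, _, _ in rows)
        templates = [
            {"domains": list(doms), "weight": w / cw, "hpt_mode": mode}
            for w, doms, mode in rows
        ]
        # renormalize away float error so the sums are exact to 1e-12
        s = math.fsum(t["weight"] for t in templates)
        for t in templates:
            t["weight"] /= s
        classes.append({"label": label, "weight": cw, "templates": templates})

    return {
        "seed": 20230920,
        "degrade_prob": 0.05,
        "split_prob": 0.05,
        "split_insert_len": 50,
        "his_loss_prob": 0.10,
        "dim_extended_prob": 0.20,
        "dim_extension_max": DIM_EXTENSION_CAP,
        "linker_len_range": [20, 40],
        "force_max_hpt_record": True,
        "max_hpt_copies": 14,
        "classes": classes,
        "genome": {
            "sink_prob": 0.25,
            "sink_class_pool": ["F3", "F5", "ACF"],
            "phosphatase_presence_sink": 60.0 / 871.0,
            "phosphatase_presence_other": 0.85,
            "other_genes_mean": 5.0,
            "contig_length_range": [20000, 80000],
            "contig_end_margin": 100,
            "intergenic_range": [50, 300],
        },
    }


def _config_from_dict(raw: Mapping[str, Any]) -> GeneratorConfig:
    required = (
        "seed",
        "degrade_prob",
        "split_prob",
        "split_insert_len",
        "his_loss_prob",
        "dim_extended_prob",
        "dim_extension_max",
        "linker_len_range",
        "classes",
    )
    for key in required:
        if key not in raw:
            raise ConfigError(f"missing required configuration key {key!r}")
    templates: list[ArchitectureTemplate] = []
    class_weights: dict[str, float] = {}
    for cls in raw["classes"]:
        for key in ("label", "weight", "templates"):
            if key not in cls:
                raise ConfigError(f"class entry missing key {key!r}")
        label = cls["label"]
        class_weights[label] = float(cls["weight"])
        for t in cls["templates"]:
            if "domains" not in t or "weight" not in t:
                raise ConfigError(f"template in class {label!r} missing 'domains' or 'weight'")
            templates.append(
                ArchitectureTemplate(
                    class_label=label,
                    domain_list=tuple(t["domains"]),
                    weight=float(t["weight"]),
                    hpt_mode=t.get("hpt_mode", "normal"),
                )
            )
    genome = GenomeParams(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("genome", {}).items()
        }
    )
    return GeneratorConfig(
        templates=tuple(templates),
        class_weights=class_weights,
        degrade_prob=float(raw["degrade_prob"]),
        split_prob=float(raw["split_prob"]),
        split_insert_len=int(raw["split_insert_len"]),
        his_loss_prob=float(raw["his_loss_prob"]),
        dim_extended_prob=float(raw["dim_extended_prob"]),
        dim_extension_max=int(raw["dim_extension_max"]),
        linker_len_range=tuple(int(x) for x in raw["linker_len_range"]),
        seed=raw["seed"],
        force_max_hpt_record=bool(raw.get("force_max_hpt_record", True)),
        max_hpt_copies=int(raw.get("max_hpt_copies", 14)),
        genome=genome,
    )


def load_paper_parameters(path: str | Path | None = None) -> GeneratorConfig:
    """Load a generator configuration file; ``None`` loads the bundled
    default parameterized at the survey's printed frequencies."""
    if path is None:
        text = resources.files("cheascope.data").joinpath("default_config.json").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        try:
            import yaml

            raw = yaml.safe_load(text)
        except Exception as exc:  # pragma: no cover - yaml fallback
            raise ConfigError(f"cannot parse configuration: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    return _config_from_dict(raw)


def default_generator_config() -> GeneratorConfig:
    """The bundled paper-parameterized configuration."""
    return _config_from_dict(build_default_config_dict())
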