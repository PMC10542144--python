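"""Domain family models for CheA architecture analysis.

Each :class:`DomainModel` couples a consensus residue string with length
bounds and, where relevant, a conserved-site annotation.  The same model
serves two purposes: the synthetic generator emits (possibly perturbed)
instances of the consensus, and the scanner scores sequence windows
against it.  The consensus strings below are *synthetic* — they are fixed
random sequences standing in for family profiles (Hpt, P2/CheY-binding,
H-kinase_dim, HATPase_c, CheW, CheY-like, CheC-like), not natural
sequences.  What matters for the pipeline is that distinct families are
mutually dissimilar and that Hpt carries a phosphorylatable histidine at
a fixed consensus position (position 48 in 1-based numbering, mirroring
His-48 of the *E. coli* reference kinase).
"""

from __future__ import annotations

from dataclasses import dataclass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Low-complexity residues used for inter-domain linkers, split-domain
#: insertions and dimerization-helix extensions.  Drawn uniformly, such
#: segments sit at ~5% identity to any consensus window and therefore
#: never reach even the sensitive detection threshold.
LINKER_ALPHABET = "GSAPT"

# Family labels (kept identical to the field's Pfam-style names).
HPT = "Hpt"
P2 = "P2"
DIM = "H-kinase_dim"
HATPASE = "HATPase_c"
CHEW = "CheW"
CHEY_LIKE = "CheY-like"
CHEC_LIKE = "CheC-like"

ALL_FAMILIES = (HPT, P2, DIM, HATPASE, CHEW, CHEY_LIKE, CHEC_LIKE)

#: The classical five-domain order of the reference kinase, N→C.
CANONICAL_ARCHITECTURE = (HPT, P2, DIM, HATPASE, CHEW)

#: The four-domain core unit shared by all homologs.
CORE_FOUR = (HPT, DIM, HATPASE, CHEW)


class ModelError(ValueError):
    """A DomainModel violates its structural invariants."""


@dataclass(frozen=True)
class DomainModel:
    """A named domain family: generative template and scoring reference.

    Parameters
    ----------
    family_name:
        One of :data:`ALL_FAMILIES`.
    consensus:
        Reference residue string.  For the dimerization domain this is
        ``helix1 + loop + helix2`` and the two helices are also exposed
        separately via ``sub_motifs``.
    min_len, max_len:
        Bounds on realized instance length (the dimerization domain can
        be extended up to ``max_len`` by inter-helix insertions).
    conserved_site_offset, conserved_site_residue:
        0-based offset into ``consensus`` of a functionally required
        residue (the Hpt histidine), or ``None``.
    sub_motifs:
        For the dimerization domain, the two helix sub-motifs.
    """

    family_name: str
    consensus: str
    min_len: int
    max_len: int
    conserved_site_offset: int | None = None
    conserved_site_residue: str | None = None
    sub_motifs: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.family_name not in ALL_FAMILIES:
            raise ModelError(f"unknown family {self.family_name!r}")
        bad = set(self.consensus) - set(AMINO_ACIDS)
        if bad:
            raise ModelError(f"{self.family_name}: non-standard residues {bad}")
        if not 0 < self.min_len <= self.max_len:
            raise ModelError(f"{self.family_name}: bad length bounds")
        if self.conserved_site_offset is not None:
            if not 0 <= self.conserved_site_offset < len(self.consensus):
                raise ModelError(f"{self.family_name}: conserved site outside consensus")
            if self.consensus[self.conserved_site_offset] != self.conserved_site_residue:
                raise ModelError(f"{self.family_name}: consensus disagrees with conserved residue")
        if self.sub_motifs is not None:
            h1, h2 = self.sub_motifs
            if not (self.consensus.startswith(h1) and self.consensus.endswith(h2)):
                raise ModelError(f"{self.family_name}: sub-motifs must flank the consensus")
            if self.min_len < len(h1) + len(h2):
                raise ModelError(f"{self.family_name}: min_len below sub-motif total")

    @property
    def length(self) -> int:
        return len(self.consensus)


# -- synthetic consensus strings (fixed; see module docstring) ---------------

_HPT_CONSENSUS = (
    "TKDIVKMIFMVAGGWPVHNCLVGKYRILLVFALSGGGILGVRNESCGHFR"
    "IHLFDLNKDECDTAQLKYSKGTHEQCDWCWKEQDDRCMSM"
)
#: 0-based consensus offset of the phosphorylatable histidine (His-48
#: equivalent; 1-based position 48).
HPT_HIS_OFFSET = 47

_P2_CONSENSUS = "TKSVMFCLTFTKWCRTPSLNNNMPPQHHRGKTSEANNHTIYGHLCFDCMIKMMRDWARVYLFIMLDMDSQ"

_DIM_HELIX1 = "RAKQIGGNKIHLRPWWQVCWWQGWGMC"
_DIM_HELIX2 = "YPQHDAVEYKTHNSHTNMHGLCQPYDT"
_DIM_LOOP = "GSPTGS"

_HATPASE_CONSENSUS = (
    "AWSFFDPNWTPMIDMNLKLFWPCVSLSQCDKDTGPVIAYEVITWARLGLH"
    "LGWADLYAKKQMFLFNLPCCVELVYQAMLVQAATQHMADWWLQNYTSKNQLEAWMAICTQ"
)

_CHEW_CONSENSUS = (
    "VLKLNAPNAPNGVISAIKTYVSSDFMGIDHSSWYYTLTEWPQMETVWEPS"
    "ETMDPFYHHEMLQYQQTDPDCHPRRHQIHYKKAPWSHNYTNKQYQGLMKE"
)

_CHEY_CONSENSUS = (
    "AEPLTQESKWWPHVITLYDTERQIKGALNDIENHFIRFQYNDQALTNEIP"
    "RMPTKSMNGYWTEWFERAKILKCIQRHVSKKTKHHRTPCNLKFCHGRVVHAGGTSDHEMGMEPCE"
)

_CHEC_CONSENSUS = (
    "YHHACQQKIWLIWHLHDHMFACAWKDNSMGQTTRCTMAQAYNAMPPHKLI"
    "RGYIHLQAFQDFIAGWGDQQDNTKDGMNWWQDGPTHHGDDEELNWCFCYK"
)

#: Length above which a dimerization domain is called "extended"
#: (classical helices span ~60–70 residues).
CLASSICAL_DIM_MAX_LEN = 70

#: Hard cap on extended dimerization length (~3x the classical domain).
DIM_EXTENSION_CAP = 170


def default_models() -> dict[str, DomainModel]:
    """The bundled model registry, keyed by family name."""
    dim_consensus = _DIM_HELIX1 + _DIM_LOOP + _DIM_HELIX2
    return {
        HPT: DomainModel(HPT, _HPT_CONSENSUS, 80, 110, HPT_HIS_OFFSET, "H"),
        P2: DomainModel(P2, _P2_CONSENSUS, 60, 90),
        DIM: DomainModel(
            DIM,
            dim_consensus,
            min_len=len(_DIM_HELIX1) + len(_DIM_HELIX2),
            max_len=DIM_EXTENSION_CAP,
            sub_motifs=(_DIM_HELIX1, _DIM_HELIX2),
        ),
        HATPASE: DomainModel(HATPASE, _HATPASE_CONSENSUS, 95, 130),
        CHEW: DomainModel(CHEW, _CHEW_CONSENSUS, 85, 120),
        CHEY_LIKE: DomainModel(CHEY_LIKE, _CHEY_CONSENSUS, 100, 135),
        CHEC_LIKE: DomainModel(CHEC_LIKE, _CHEC_CONSENSUS, 85, 120),
    }
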