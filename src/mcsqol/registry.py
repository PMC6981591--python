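"""Registry of the assayed detoxification-gene polymorphisms.

The panel covers xenobiotic-metabolism phase I enzymes (CYP2C9, CYP2C19,
CYP2D6, UGT1A1), phase II / antioxidant-defence enzymes (GSTs, SOD2, CAT,
OGG1, PON1, NOS3, MPO) and the folate-cycle enzyme MTHFR.  For composite
scoring the variants are grouped into three functional classes:

* ``MTHFR``   — MTHFR C677T and A1298C;
* ``phaseI``  — CYP2D6 and CYP2C19 (phenotype-level entries), UGT1A1*28,
  CYP2C9 A1075T (*3) and CYP2C9 C430T (*2);
* ``phaseII`` — MPO, GSTP1, GSTM1/GSTT1 deletions, SOD2, CAT, OGG1,
  both PON1 sites and eNOS (NOS3).

The class membership follows the study design this package models, not
biochemical intuition (UGT1A1*28 sits in the phase I class, the antioxidant
enzymes in phase II).

CYP2D6 and CYP2C19 are *phenotype-level* registry entries: each aggregates
several genotyped sites (listed in ``assay_sites``) into one star-allele
diplotype that is translated to a metabolizer phenotype before scoring.
Counting sites instead of entries, the panel comprises 20 SNP/sequencing
assays plus the two multiplex-PCR deletion assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class AssayKind(str, Enum):
    BIALLELIC_SNP = "biallelic_snp"
    DELETION_PRESENCE = "deletion_presence"
    STAR_DIPLOTYPE = "star_diplotype"
    TA_REPEAT = "ta_repeat"


class VariantClass(str, Enum):
    MTHFR = "MTHFR"
    PHASE_I = "phaseI"
    PHASE_II = "phaseII"


@dataclass(frozen=True)
class PolymorphismDef:
    """Definition of one scored polymorphism.

    Parameters
    ----------
    gene : str
        HGNC-style gene symbol.
    variant_id : str
        Canonical identifier used in input tables.
    assay_kind : AssayKind
        How the variant is assayed/encoded.
    alleles : tuple of str
        Allowed allele labels, wild-type first.
    class_membership : VariantClass
        Functional class the variant's score contributes to.
    aliases : tuple of str
        Accepted synonyms for ``variant_id`` (rsIDs, star names).
    assay_sites : tuple of str
        Underlying genotyped sites (one per SNP assay).
    """

    gene: str
    variant_id: str
    assay_kind: AssayKind
    alleles: tuple[str, ...]
    class_membership: VariantClass
    aliases: tuple[str, ...] = ()
    assay_sites: tuple[str, ...] = field(default=())

    @property
    def wildtype(self) -> str:
        return self.alleles[0]

    def __post_init__(self) -> None:
        if not self.assay_sites and self.assay_kind is not AssayKind.DELETION_PRESENCE:
            object.__setattr__(self, "assay_sites", (self.variant_id,))


DELETION_PRESENT = "present"
DELETION_NULL = "null"

_REGISTRY_ENTRIES: tuple[PolymorphismDef, ...] = (
    # --- MTHFR class -----------------------------------------------------
    PolymorphismDef("MTHFR", "MTHFR_C677T", AssayKind.BIALLELIC_SNP,
                    ("C", "T"), VariantClass.MTHFR, aliases=("rs1801133",)),
    PolymorphismDef("MTHFR", "MTHFR_A1298C", AssayKind.BIALLELIC_SNP,
                    ("A", "C"), VariantClass.MTHFR, aliases=("rs1801131",)),
    # --- phase I class ---------------------------------------------------
    PolymorphismDef("CYP2D6", "CYP2D6", AssayKind.STAR_DIPLOTYPE,
                    ("*1", "*2", "*2A", "*2xN", "*10", "*41", "*4", "*6"),
                    VariantClass.PHASE_I,
                    assay_sites=("CYP2D6_C2850T", "CYP2D6_C1584G",
                                 "CYP2D6_G1846A", "CYP2D6_G2988A",
                                 "CYP2D6_C100T")),
    PolymorphismDef("CYP2C19", "CYP2C19", AssayKind.STAR_DIPLOTYPE,
                    ("*1", "*17", "*2"), VariantClass.PHASE_I,
                    assay_sites=("CYP2C19_G681A", "CYP2C19_C806T")),
    PolymorphismDef("UGT1A1", "UGT1A1_28", AssayKind.TA_REPEAT,
                    ("6", "7", "8"), VariantClass.PHASE_I,
                    aliases=("rs8175347", "UGT1A1*28")),
    PolymorphismDef("CYP2C9", "CYP2C9_A1075T", AssayKind.BIALLELIC_SNP,
                    ("A", "T"), VariantClass.PHASE_I,
                    aliases=("rs1057910", "CYP2C9*3")),
    PolymorphismDef("CYP2C9", "CYP2C9_C430T", AssayKind.BIALLELIC_SNP,
                    ("C", "T"), VariantClass.PHASE_I,
                    aliases=("rs1799853", "CYP2C9*2")),
    # --- phase II class --------------------------------------------------
    PolymorphismDef("MPO", "MPO_G463A", AssayKind.BIALLELIC_SNP,
                    ("G", "A"), VariantClass.PHASE_II, aliases=("rs2333227",)),
    PolymorphismDef("GSTP1", "GSTP1_A313G", AssayKind.BIALLELIC_SNP,
                    ("A", "G"), VariantClass.PHASE_II, aliases=("rs1695",)),
    PolymorphismDef("GSTM1", "GSTM1_DEL", AssayKind.DELETION_PRESENCE,
                    (DELETION_PRESENT, DELETION_NULL), VariantClass.PHASE_II),
    PolymorphismDef("GSTT1", "GSTT1_DEL", AssayKind.DELETION_PRESENCE,
                    (DELETION_PRESENT, DELETION_NULL), VariantClass.PHASE_II),
    PolymorphismDef("SOD2", "SOD2_C48T", AssayKind.BIALLELIC_SNP,
                    ("C", "T"), VariantClass.PHASE_II,
                    aliases=("rs4880", "SOD2_A16V")),
    PolymorphismDef("CAT", "CAT_C262T", AssayKind.BIALLELIC_SNP,
                    ("C", "T"), VariantClass.PHASE_II, aliases=("rs1001179",)),
    PolymorphismDef("OGG1", "OGG1_C315G", AssayKind.BIALLELIC_SNP,
                    ("C", "G"), VariantClass.PHASE_II,
                    aliases=("rs1052133", "OGG1_S326C")),
    PolymorphismDef("PON1", "PON1_A575G", AssayKind.BIALLELIC_SNP,
                    ("A", "G"), VariantClass.PHASE_II,
                    aliases=("rs662", "PON1_Q192R")),
    PolymorphismDef("PON1", "PON1_C108T", AssayKind.BIALLELIC_SNP,
                    ("C", "T"), VariantClass.PHASE_II,
                    aliases=("rs705379", "PON1_L55M")),
    PolymorphismDef("NOS3", "NOS3_G894T", AssayKind.BIALLELIC_SNP,
                    ("G", "T"), VariantClass.PHASE_II,
                    aliases=("rs1799983", "eNOS_D298E")),
)


def default_registry() -> dict[str, PolymorphismDef]:
    """Return the default scoring registry keyed by ``variant_id``.

    17 scoring entries (2 MTHFR, 5 phase I, 10 phase II); the underlying
    SNP/sequencing assay sites number 20.
    """
    return {p.variant_id: p for p in _REGISTRY_ENTRIES}


def resolve_variant_id(label: str, registry: dict[str, PolymorphismDef]) -> str:
    """Resolve a variant label or alias to its canonical ``variant_id``.

    Raises ``KeyError`` if the label matches nothing in the registry.
    """
    if label in registry:
        return label
    for vid, pdef in registry.items():
        if label in pdef.aliases:
            return vid
    raise KeyError(f"unknown variant_id {label!r}")
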