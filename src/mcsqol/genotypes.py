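"""Genotype encodings, metabolizer-phenotype calling and class scores.

Per-variant encodings
---------------------
* biallelic SNPs and the UGT1A1 TA-repeat: number of non-wild-type alleles
  (wild-type 0, heterozygote 1, mutated homozygote 2);
* GSTM1/GSTT1 presence/deletion assays: gene present 0, null 1 (the
  multiplex assay cannot distinguish heterozygous carriers, so "null"
  means homozygous deletion);
* CYP2D6 and CYP2C19: the star-allele diplotype is translated to a
  metabolizer phenotype, scored UM → −1, EM → 0, IM → 1, PM → 2.

Class scores are sums of member-variant scores: MTHFR ∈ [0, 4],
phase I ∈ [−2, 10], phase II ∈ [0, 18].  Higher scores mean a heavier
burden of reduced-function detoxification variants.

Phenotype calling uses per-allele function assignments
(increased / functional / reduced / null) combined pairwise:

* any increased-function allele (e.g. a *2xN duplication) → UM;
* otherwise ≥1 functional allele → EM (functional/functional,
  functional/reduced, functional/null);
* reduced/reduced or reduced/null → IM;
* null/null → PM.

For CYP2C19 the common clinical translation differs from the naive
function-pair rule (a single *2 loss-of-function allele is conventionally
an intermediate, not extensive, metabolizer), so a per-gene diplotype
override table takes precedence; the default override implements
*1/*1→EM, *1/*2→IM, *2/*2→PM, *1/*17→UM, *17/*17→UM, *2/*17→IM.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .registry import (
    DELETION_NULL,
    DELETION_PRESENT,
    AssayKind,
    PolymorphismDef,
    VariantClass,
    default_registry,
)


class AlleleFunction(str, Enum):
    INCREASED = "increased"
    FUNCTIONAL = "functional"
    REDUCED = "reduced"
    NULL = "null"


class MetabolizerPhenotype(str, Enum):
    UM = "UM"  # ultrarapid
    EM = "EM"  # extensive (normal)
    IM = "IM"  # intermediate
    PM = "PM"  # poor


#: phenotype → score used inside the phase I class composite
PHENOTYPE_SCORES: dict[MetabolizerPhenotype, int] = {
    MetabolizerPhenotype.UM: -1,
    MetabolizerPhenotype.EM: 0,
    MetabolizerPhenotype.IM: 1,
    MetabolizerPhenotype.PM: 2,
}

F = AlleleFunction
DEFAULT_ALLELE_FUNCTIONS: dict[str, dict[str, AlleleFunction]] = {
    "CYP2D6": {
        "*1": F.FUNCTIONAL, "*2": F.FUNCTIONAL, "*2A": F.FUNCTIONAL,
        "*2xN": F.INCREASED,
        "*10": F.REDUCED, "*41": F.REDUCED,
        "*4": F.NULL, "*6": F.NULL,
    },
    "CYP2C19": {"*1": F.FUNCTIONAL, "*17": F.INCREASED, "*2": F.NULL},
}

#: per-gene diplotype translations taking precedence over the pair rule;
#: keys are frozensets so allele order is irrelevant (homozygotes collapse
#: to a single-element set)
DEFAULT_DIPLOTYPE_OVERRIDES: dict[str, dict[frozenset, MetabolizerPhenotype]] = {
    "CYP2C19": {
        frozenset({"*1"}): MetabolizerPhenotype.EM,
        frozenset({"*1", "*2"}): MetabolizerPhenotype.IM,
        frozenset({"*2"}): MetabolizerPhenotype.PM,
        frozenset({"*1", "*17"}): MetabolizerPhenotype.UM,
        frozenset({"*17"}): MetabolizerPhenotype.UM,
        frozenset({"*2", "*17"}): MetabolizerPhenotype.IM,
    },
}


@dataclass(frozen=True)
class GenotypeCall:
    """One patient's genotype at one registry variant.

    ``alleles`` holds the unordered allele pair for SNP / repeat /
    star-diplotype assays, or a single presence flag
    (``present`` / ``null``) for the deletion assays.
    """

    patient_id: str
    variant_id: str
    alleles: tuple[str, ...]

    def validate(self, pdef: PolymorphismDef) -> None:
        if pdef.assay_kind is AssayKind.DELETION_PRESENCE:
            if len(self.alleles) != 1 or self.alleles[0] not in pdef.alleles:
                raise ValueError(
                    f"{self.variant_id} for patient {self.patient_id}: deletion "
                    f"assays carry exactly one of {pdef.alleles}, got {self.alleles}")
            return
        if len(self.alleles) != 2:
            raise ValueError(
                f"{self.variant_id} for patient {self.patient_id}: expected an "
                f"allele pair, got {self.alleles}")
        bad = [a for a in self.alleles if a not in pdef.alleles]
        if bad:
            raise ValueError(
                f"{self.variant_id} for patient {self.patient_id}: allele(s) {bad} "
                f"not in allele set {pdef.alleles}")


def score_biallelic(call: GenotypeCall, pdef: PolymorphismDef) -> int:
    """Gene-dose score 0/1/2: the number of non-wild-type alleles.

    For the UGT1A1 TA-repeat, any allele with ≥7 repeats counts as a
    *28-like mutant (the 8-repeat allele is scored like 7).
    """
    if pdef.assay_kind not in (AssayKind.BIALLELIC_SNP, AssayKind.TA_REPEAT):
        raise ValueError(f"{pdef.variant_id} is not a gene-dose scored assay")
    call.validate(pdef)
    if pdef.assay_kind is AssayKind.TA_REPEAT:
        return sum(1 for a in call.alleles if int(a) >= 7)
    return sum(1 for a in call.alleles if a != pdef.wildtype)


def score_deletion(call: GenotypeCall, pdef: PolymorphismDef) -> int:
    """Deletion score: gene present → 0, null (deleted) → 1."""
    if pdef.assay_kind is not AssayKind.DELETION_PRESENCE:
        raise ValueError(f"{pdef.variant_id} is not a presence/deletion assay")
    call.validate(pdef)
    return 0 if call.alleles[0] == DELETION_PRESENT else 1


def call_metabolizer(
    gene: str,
    diplotype: tuple[str, str],
    allele_functions: dict[str, dict[str, AlleleFunction]] | None = None,
    diplotype_overrides: dict[str, dict[frozenset, MetabolizerPhenotype]] | None = None,
) -> MetabolizerPhenotype:
    """Translate a star-allele diplotype into a metabolizer phenotype.

    Symmetric in allele order.  Raises ``KeyError`` for alleles without a
    function assignment.
    """
    functions = (allele_functions or DEFAULT_ALLELE_FUNCTIONS)[gene]
    overrides = (DEFAULT_DIPLOTYPE_OVERRIDES if diplotype_overrides is None
                 else diplotype_overrides).get(gene, {})
    a, b = diplotype
    for allele in (a, b):
        if allele not in functions:
            raise KeyError(f"{gene}: no function assigned to allele {allele!r}")
    key = frozenset({a, b})
    if key in overrides:
        return overrides[key]
    fa, fb = functions[a], functions[b]
    pair = {fa, fb}
    if F.INCREASED in pair:
        return MetabolizerPhenotype.UM
    if F.FUNCTIONAL in pair:
        return MetabolizerPhenotype.EM
    if pair == {F.NULL}:
        return MetabolizerPhenotype.PM
    return MetabolizerPhenotype.IM  # reduced/reduced or reduced/null


def phenotype_to_score(ph: MetabolizerPhenotype) -> int:
    """UM → −1, EM → 0, IM → 1, PM → 2."""
    return PHENOTYPE_SCORES[MetabolizerPhenotype(ph)]


def score_variant(
    call: GenotypeCall,
    pdef: PolymorphismDef,
    allele_functions: dict[str, dict[str, AlleleFunction]] | None = None,
    diplotype_overrides: dict[str, dict[frozenset, MetabolizerPhenotype]] | None = None,
) -> int:
    """Dispatch a genotype call to the encoding its assay kind prescribes."""
    if pdef.assay_kind is AssayKind.DELETION_PRESENCE:
        return score_deletion(call, pdef)
    if pdef.assay_kind is AssayKind.STAR_DIPLOTYPE:
        call.validate(pdef)
        ph = call_metabolizer(pdef.gene, (call.alleles[0], call.alleles[1]),
                              allele_functions, diplotype_overrides)
        return phenotype_to_score(ph)
    return score_biallelic(call, pdef)


@dataclass(frozen=True)
class ClassScore:
    patient_id: str
    mthfr_score: int
    phase1_score: int
    phase2_score: int


def class_scores(
    genotypes: dict[str, GenotypeCall],
    registry: dict[str, PolymorphismDef] | None = None,
    *,
    allele_functions: dict[str, dict[str, AlleleFunction]] | None = None,
    diplotype_overrides: dict[str, dict[frozenset, MetabolizerPhenotype]] | None = None,
    missing_as_wildtype: bool = False,
    patient_id: str | None = None,
) -> ClassScore:
    """Sum per-variant scores into the three functional class composites.

    ``genotypes`` maps variant_id → call for one patient.  A registry
    variant without a call is a hard error unless ``missing_as_wildtype``
    is set, in which case it contributes 0 (wild-type / EM).
    """
    registry = registry if registry is not None else default_registry()
    pid = patient_id
    totals = {VariantClass.MTHFR: 0, VariantClass.PHASE_I: 0, VariantClass.PHASE_II: 0}
    for vid, pdef in registry.items():
        call = genotypes.get(vid)
        if call is None:
            if missing_as_wildtype:
                continue
            raise ValueError(
                f"patient {pid or '?'}: missing genotype for {vid} "
                f"(pass missing_as_wildtype=True to score it as wild-type)")
        if pid is None:
            pid = call.patient_id
        totals[pdef.class_membership] += score_variant(
            call, pdef, allele_functions, diplotype_overrides)
    return ClassScore(pid or "?", totals[VariantClass.MTHFR],
                      totals[VariantClass.PHASE_I], totals[VariantClass.PHASE_II])
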