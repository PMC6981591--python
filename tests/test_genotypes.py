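"""Genotype encodings, metabolizer calling and class-score composition."""

import itertools

import pytest

from mcsqol import (
    GenotypeCall,
    MetabolizerPhenotype,
    call_metabolizer,
    class_scores,
    default_registry,
    phenotype_to_score,
    score_biallelic,
    score_deletion,
    score_variant,
)
from mcsqol.genotypes import DEFAULT_ALLELE_FUNCTIONS, AlleleFunction
from mcsqol.registry import DELETION_NULL, DELETION_PRESENT

REG = default_registry()
UM, EM, IM, PM = (MetabolizerPhenotype.UM, MetabolizerPhenotype.EM,
                  MetabolizerPhenotype.IM, MetabolizerPhenotype.PM)


@pytest.mark.parametrize("vid,alleles,expected", [
    ("MTHFR_C677T", ("C", "T"), 1),
    ("MTHFR_C677T", ("T", "T"), 2),
    ("SOD2_C48T", ("C", "C"), 0),
    ("UGT1A1_28", ("7", "7"), 2),   # *28/*28 homozygote
    ("UGT1A1_28", ("6", "7"), 1),
    ("UGT1A1_28", ("7", "8"), 2),   # 8 repeats scored as *28-like
])
def test_gene_dose_scoring(vid, alleles, expected):
    call = GenotypeCall("P1", vid, alleles)
    assert score_biallelic(call, REG[vid]) == expected
    # symmetric in allele order
    assert score_biallelic(GenotypeCall("P1", vid, alleles[::-1]), REG[vid]) == expected


def test_biallelic_rejects_foreign_allele():
    with pytest.raises(ValueError, match="allele"):
        score_biallelic(GenotypeCall("P1", "MTHFR_C677T", ("C", "G")),
                        REG["MTHFR_C677T"])


@pytest.mark.parametrize("state,expected", [
    (DELETION_PRESENT, 0),
    (DELETION_NULL, 1),
])
def test_deletion_scoring(state, expected):
    call = GenotypeCall("P1", "GSTM1_DEL", (state,))
    assert score_deletion(call, REG["GSTM1_DEL"]) == expected


def test_deletion_rejects_allele_pair():
    with pytest.raises(ValueError, match="deletion"):
        score_deletion(GenotypeCall("P1", "GSTM1_DEL", ("*1", "*2")),
                       REG["GSTM1_DEL"])


@pytest.mark.parametrize("diplotype,expected", [
    (("*4", "*4"), PM),     # null/null
    (("*1", "*4"), EM),     # functional/null
    (("*1", "*1"), EM),
    (("*2", "*41"), EM),    # functional/reduced
    (("*10", "*41"), IM),   # reduced/reduced
    (("*41", "*4"), IM),    # reduced/null
    (("*2", "*2xN"), UM),   # duplication dominates
    (("*2xN", "*4"), UM),
])
def test_cyp2d6_calls(diplotype, expected):
    assert call_metabolizer("CYP2D6", diplotype) is expected
    assert call_metabolizer("CYP2D6", diplotype[::-1]) is expected


@pytest.mark.parametrize("diplotype,expected", [
    (("*1", "*1"), EM),
    (("*1", "*2"), IM),     # clinical override: one LoF allele → IM
    (("*2", "*2"), PM),
    (("*1", "*17"), UM),
    (("*17", "*17"), UM),
    (("*2", "*17"), IM),
])
def test_cyp2c19_translation(diplotype, expected):
    assert call_metabolizer("CYP2C19", diplotype) is expected


def test_cyp2d6_exhaustive_function_pair_rule():
    """Every diplotype over the default allele table obeys the pair rule."""
    functions = DEFAULT_ALLELE_FUNCTIONS["CYP2D6"]
    for a, b in itertools.combinations_with_replacement(functions, 2):
        ph = call_metabolizer("CYP2D6", (a, b))
        fa, fb = functions[a], functions[b]
        pair = {fa, fb}
        if AlleleFunction.INCREASED in pair:
            assert ph is UM
        elif AlleleFunction.FUNCTIONAL in pair:
            assert ph is EM
        elif pair == {AlleleFunction.NULL}:
            assert ph is PM
        else:
            assert ph is IM


def test_unknown_allele_rejected():
    with pytest.raises(KeyError, match="\\*99"):
        call_metabolizer("CYP2D6", ("*1", "*99"))


def test_phenotype_scores():
    assert [phenotype_to_score(p) for p in (UM, EM, IM, PM)] == [-1, 0, 1, 2]


# ---------------------------------------------------------------------------
# class composites
# ---------------------------------------------------------------------------

def _wildtype_calls():
    calls = {}
    for vid, pdef in REG.items():
        if pdef.assay_kind.value == "deletion_presence":
            alleles = (DELETION_PRESENT,)
        elif pdef.assay_kind.value == "star_diplotype":
            alleles = ("*1", "*1")
        else:
            alleles = (pdef.wildtype, pdef.wildtype)
        calls[vid] = GenotypeCall("P1", vid, alleles)
    return calls


def test_all_wildtype_scores_zero():
    cs = class_scores(_wildtype_calls())
    assert (cs.mthfr_score, cs.phase1_score, cs.phase2_score) == (0, 0, 0)


def test_mthfr_composite():
    """677 TT + 1298 AC → 2 + 1 = 3."""
    calls = _wildtype_calls()
    calls["MTHFR_C677T"] = GenotypeCall("P1", "MTHFR_C677T", ("T", "T"))
    calls["MTHFR_A1298C"] = GenotypeCall("P1", "MTHFR_A1298C", ("A", "C"))
    assert class_scores(calls).mthfr_score == 3


def test_phase1_composite():
    """CYP2D6 PM + CYP2C19 EM + UGT1A1 6/7 + CYP2C9 *1/*3 + *1/*2 → 5."""
    calls = _wildtype_calls()
    calls["CYP2D6"] = GenotypeCall("P1", "CYP2D6", ("*4", "*4"))
    calls["UGT1A1_28"] = GenotypeCall("P1", "UGT1A1_28", ("6", "7"))
    calls["CYP2C9_A1075T"] = GenotypeCall("P1", "CYP2C9_A1075T", ("A", "T"))
    calls["CYP2C9_C430T"] = GenotypeCall("P1", "CYP2C9_C430T", ("C", "T"))
    assert class_scores(calls).phase1_score == 2 + 0 + 1 + 1 + 1


def test_phase1_floor_is_minus_two():
    calls = _wildtype_calls()
    calls["CYP2D6"] = GenotypeCall("P1", "CYP2D6", ("*2", "*2xN"))
    calls["CYP2C19"] = GenotypeCall("P1", "CYP2C19", ("*17", "*17"))
    assert class_scores(calls).phase1_score == -2


def test_class_score_equals_bruteforce_lookup():
    """Composite equals an independently coded per-variant score lookup."""
    calls = _wildtype_calls()
    calls["MTHFR_C677T"] = GenotypeCall("P1", "MTHFR_C677T", ("C", "T"))
    calls["CYP2D6"] = GenotypeCall("P1", "CYP2D6", ("*10", "*4"))      # IM → 1
    calls["CYP2C19"] = GenotypeCall("P1", "CYP2C19", ("*1", "*17"))    # UM → -1
    calls["GSTM1_DEL"] = GenotypeCall("P1", "GSTM1_DEL", (DELETION_NULL,))
    calls["SOD2_C48T"] = GenotypeCall("P1", "SOD2_C48T", ("T", "T"))
    calls["PON1_C108T"] = GenotypeCall("P1", "PON1_C108T", ("C", "T"))
    # independent oracle: hand-listed expected per-variant scores
    expected = {"MTHFR_C677T": 1, "CYP2D6": 1, "CYP2C19": -1,
                "GSTM1_DEL": 1, "SOD2_C48T": 2, "PON1_C108T": 1}
    cs = class_scores(calls)
    assert cs.mthfr_score == expected["MTHFR_C677T"]
    assert cs.phase1_score == expected["CYP2D6"] + expected["CYP2C19"]
    assert cs.phase2_score == (expected["GSTM1_DEL"] + expected["SOD2_C48T"]
                               + expected["PON1_C108T"])
    for vid, want in expected.items():
        assert score_variant(calls[vid], REG[vid]) == want


def test_class_score_bounds_extremes():
    """Worst-case genotypes hit the documented class-score ceilings."""
    calls = {}
    for vid, pdef in REG.items():
        if pdef.assay_kind.value == "deletion_presence":
            alleles = (DELETION_NULL,)
        elif vid == "CYP2D6":
            alleles = ("*4", "*4")
        elif vid == "CYP2C19":
            alleles = ("*2", "*2")
        elif pdef.assay_kind.value == "ta_repeat":
            alleles = ("7", "7")
        else:
            alleles = (pdef.alleles[1], pdef.alleles[1])
        calls[vid] = GenotypeCall("P1", vid, alleles)
    cs = class_scores(calls)
    assert (cs.mthfr_score, cs.phase1_score, cs.phase2_score) == (4, 10, 18)


def test_missing_variant_is_hard_error():
    calls = _wildtype_calls()
    del calls["CAT_C262T"]
    with pytest.raises(ValueError, match="CAT_C262T"):
        class_scores(calls)
    # opt-in wild-type imputation scores the gap as 0
    assert class_scores(calls, missing_as_wildtype=True).phase2_score == 0
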