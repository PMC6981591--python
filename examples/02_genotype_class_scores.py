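"""Score a genotype panel into the three functional class composites.

Reads a small genotype table (TSV text), calls the CYP metabolizer
phenotypes and sums the per-variant scores into the MTHFR, phase I and
phase II class scores used as regression factors x1-x3.
"""

import io

from mcsqol import (
    call_metabolizer,
    class_scores,
    default_registry,
    read_genotype_table,
)

TSV = """patient_id\tgene\tvariant_id\tgenotype
P01\tMTHFR\tMTHFR_C677T\tT/T
P01\tMTHFR\tMTHFR_A1298C\tA/C
P01\tCYP2D6\tCYP2D6\t*4/*4
P01\tCYP2C19\tCYP2C19\t*1/*1
P01\tUGT1A1\tUGT1A1_28\t6/7
P01\tCYP2C9\tCYP2C9_A1075T\tA/T
P01\tCYP2C9\tCYP2C9_C430T\tC/T
P01\tMPO\tMPO_G463A\tG/A
P01\tGSTP1\tGSTP1_A313G\tA/A
P01\tGSTM1\tGSTM1_DEL\tnull
P01\tGSTT1\tGSTT1_DEL\tpresent
P01\tSOD2\tSOD2_C48T\tT/T
P01\tCAT\tCAT_C262T\tC/C
P01\tOGG1\tOGG1_C315G\tC/C
P01\tPON1\tPON1_A575G\tA/G
P01\tPON1\tPON1_C108T\tC/T
P01\tNOS3\tNOS3_G894T\tG/G
"""

registry = default_registry()
calls = {c.variant_id: c for c in read_genotype_table(io.StringIO(TSV), registry)}

cyp2d6 = calls["CYP2D6"]
print("CYP2D6", "/".join(cyp2d6.alleles), "->",
      call_metabolizer("CYP2D6", (cyp2d6.alleles[0], cyp2d6.alleles[1])).value,
      "(two null alleles: poor metabolizer, scored 2)")

cs = class_scores(calls, registry)
print(f"MTHFR class score   (x1): {cs.mthfr_score}   (range 0-4)")
print(f"phase II class score(x2): {cs.phase2_score}   (range 0-18)")
print(f"phase I class score (x3): {cs.phase1_score}   (range -2-10)")
print("Each class score counts reduced-function detoxification variants; "
      "higher scores entered the model as a heavier genetic burden.")
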