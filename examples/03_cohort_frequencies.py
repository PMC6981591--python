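"""Genotype/allele frequency tables and a Fisher exact reference comparison.

Simulates a study-sized cohort, tabulates one variant and compares its
genotype classes against reference-population frequencies.
"""

from mcsqol import (
    GenotypeCall,
    default_registry,
    compare_vs_reference,
    generate_cohort,
    genotype_frequencies,
)

registry = default_registry()
cohort = generate_cohort(seed=7)  # n=46, published allele frequencies

calls = [GenotypeCall(r.patient_id, r.variant_id, tuple(r.genotype.split("/")))
         for r in cohort.genotypes.itertuples()]

table = genotype_frequencies(calls, registry["CYP2C9_C430T"])
print("CYP2C9 C430T (*2) in the simulated cohort (n=%d):" % table.n)
for g, pct in sorted(table.genotype_percentages.items()):
    print(f"  {g:4s} {pct:5.1f}%")
print("  mutant allele frequency:",
      round(table.allele_frequencies.get("T", 0.0), 3))

# reference genotype frequencies for a general Caucasian population
reference = {"C/C": 0.80, "C/T": 0.172, "T/T": 0.028}
cmp = compare_vs_reference(table, reference, n_ref=500)
print("\nFisher exact comparison vs reference (n_ref=500):")
print(cmp[["genotype", "cohort_count", "reference_freq", "p_value"]]
      .to_string(index=False))
print("\nSmall p-values flag genotype classes over/under-represented in "
      "the cohort relative to the reference population.")
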