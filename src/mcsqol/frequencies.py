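"""Cohort genotype/allele frequency tables and Fisher exact comparisons.

Genotype frequencies are simple proportions over the genotyped patients;
allele frequencies are derived by gene-dose counting (each patient
contributes two alleles for SNP/repeat/diplotype assays, one
presence/null state for the deletion assays).  Cohort counts are
compared against published reference-population frequencies with a
two-sided Fisher exact test on the implied 2×2 table.  Reference cohort
sizes are usually not printed alongside reference frequencies, so
``n_ref`` is an explicit input (default 1000, with a logged caveat):
the resulting p-values depend on it and are not exact reproductions of
any published comparison.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
import scipy.stats as st

from .genotypes import GenotypeCall
from .registry import AssayKind, PolymorphismDef

logger = logging.getLogger(__name__)

DEFAULT_N_REF = 1000


def _genotype_label(call: GenotypeCall, pdef: PolymorphismDef) -> str:
    if pdef.assay_kind is AssayKind.DELETION_PRESENCE:
        return call.alleles[0]
    # order alleles by the registry's allele ordering (wild-type first)
    order = {a: i for i, a in enumerate(pdef.alleles)}
    pair = sorted(call.alleles, key=lambda a: order[a])
    return "/".join(pair)


@dataclass
class FrequencyTable:
    """Genotype and allele distribution of one variant in the cohort."""

    variant_id: str
    n: int
    genotype_counts: dict[str, int]
    allele_counts: dict[str, int]

    @property
    def genotype_percentages(self) -> dict[str, float]:
        return {g: 100.0 * c / self.n for g, c in self.genotype_counts.items()}

    @property
    def allele_frequencies(self) -> dict[str, float]:
        total = sum(self.allele_counts.values())
        return {a: c / total for a, c in self.allele_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant_id": self.variant_id, "kind": "genotype", "label": g,
                 "count": c, "value": 100.0 * c / self.n}
                for g, c in self.genotype_counts.items()]
        freqs = self.allele_frequencies
        rows += [{"variant_id": self.variant_id, "kind": "allele", "label": a,
                  "count": c, "value": freqs[a]}
                 for a, c in self.allele_counts.items()]
        return pd.DataFrame(rows)


def genotype_frequencies(
    calls: list[GenotypeCall], pdef: PolymorphismDef
) -> FrequencyTable:
    """Tabulate genotype and allele frequencies for one variant.

    Raises ``ValueError`` when no patient is genotyped at the variant.
    """
    calls = [c for c in calls if c.variant_id == pdef.variant_id]
    if not calls:
        raise ValueError(f"no genotyped patients for {pdef.variant_id}")
    for c in calls:
        c.validate(pdef)
    genotype_counts: Counter[str] = Counter(_genotype_label(c, pdef) for c in calls)
    allele_counts: Counter[str] = Counter()
    for c in calls:
        allele_counts.update(c.alleles)
    return FrequencyTable(pdef.variant_id, len(calls),
                          dict(genotype_counts), dict(allele_counts))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_vs_reference(
    k: int, n: int, p_ref: float, n_ref: int | None = None
) -> float:
    """Two-sided Fisher exact p for cohort count k/n vs a reference frequency.

    The reference column is reconstructed as round(p_ref·n_ref) successes
    out of ``n_ref`` (half-away-from-zero rounding).  Two-sidedness uses
    the minimum-likelihood rule (all tables with point probability ≤ the
    observed one), matching standard statistical packages.
    """
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError(f"reference frequency {p_ref} outside [0, 1]")
    if not 0 <= k <= n:
        raise ValueError(f"cohort count {k} outside [0, {n}]")
    if n_ref is None:
        n_ref = DEFAULT_N_REF
        logger.warning(
            "reference cohort size not given; defaulting to n_ref=%d — "
            "the p-value depends on this choice", n_ref)
    k_ref = _round_half_away(p_ref * n_ref)
    _, p = st.fisher_exact([[k, n - k], [k_ref, n_ref - k_ref]],
                           alternative="two-sided")
    return float(p)


def compare_vs_reference(
    table: FrequencyTable,
    reference: dict[str, float],
    n_ref: int | None = None,
) -> pd.DataFrame:
    """Fisher comparison of every genotype class against reference frequencies.

    ``reference`` maps genotype label → reference-population frequency
    (fractions, not percent).  Labels absent from the cohort count as 0/n.
    """
    rows = []
    for label, p_ref in reference.items():
        k = table.genotype_counts.get(label, 0)
        rows.append({
            "variant_id": table.variant_id,
            "genotype": label,
            "cohort_count": k,
            "cohort_n": table.n,
            "reference_freq": p_ref,
            "reference_n": n_ref if n_ref is not None else DEFAULT_N_REF,
            "p_value": fisher_vs_reference(k, table.n, p_ref, n_ref),
        })
    return pd.DataFrame(rows)


def phenotype_frequencies(phenotypes: list) -> dict[str, float]:
    """Fractions of UM/EM/IM/PM among called metabolizer phenotypes."""
    if not phenotypes:
        raise ValueError("no phenotypes called")
    counts = Counter(str(getattr(p, "value", p)) for p in phenotypes)
    n = len(phenotypes)
    return {ph: counts.get(ph, 0) / n for ph in ("UM", "EM", "IM", "PM")}
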