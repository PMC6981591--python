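"""Reference values from the 46-patient MCS cohort this package models.

These constants are the published summary of the original cohort: the
nine-factor regression coefficient vector, the factor means and sample
standard deviations (as used by the prediction profiler), the outcome
summary, and the genotype/exposure frequencies the synthetic-cohort
generator emulates.  They let every downstream artifact (profiles,
cut-offs) be recomputed without the undeposited patient data.
"""

from __future__ import annotations

import math

import numpy as np

#: regression factor order x1..x9
FACTOR_NAMES: tuple[str, ...] = (
    "mthfr_score",          # x1  MTHFR class composite
    "phase2_score",         # x2  phase II class composite
    "phase1_score",         # x3  phase I class composite
    "compounds_exposure",   # x4  prior chemical-compound exposure (0/1)
    "psychological_trauma", # x5  prior psychological trauma (0/1)
    "physical_trauma",      # x6  prior physical trauma (0/1)
    "previous_surgery",     # x7  prior surgery (0/1)
    "age",                  # x8  years
    "gender",               # x9  0 male, 1 female
)

FACTOR_LABELS: dict[str, str] = {
    "mthfr_score": "MTHFR enzymes score",
    "phase2_score": "Phase II enzymes score",
    "phase1_score": "Phase I enzymes score",
    "compounds_exposure": "Compounds exposure",
    "psychological_trauma": "Psychological trauma",
    "physical_trauma": "Physical trauma",
    "previous_surgery": "Previous surgery",
    "age": "Age",
    "gender": "Gender",
}

#: intercept followed by the slopes for x1..x9
STUDY_COEFFICIENTS: np.ndarray = np.array([
    18.63568,   # intercept
    0.87996,    # MTHFR class score
    0.40192,    # phase II class score
    1.09827,    # phase I class score
    2.53639,    # compounds exposure
    1.25605,    # psychological trauma
    -0.28221,   # physical trauma
    1.89423,    # previous surgery
    0.04117,    # age
    0.81441,    # gender
])

#: factor means = the profiler's center levels
STUDY_FACTOR_MEANS: np.ndarray = np.array([
    1.326087, 5.847826, 1.5, 0.5217391, 0.5217391,
    0.3695652, 0.3043478, 47.23913, 0.5869565,
])

#: factor sample SDs (n−1 denominator) = the profiler's grid spacings
STUDY_FACTOR_SDS: np.ndarray = np.array([
    0.844705, 2.476264, 1.110555, 0.5050469, 0.5050469,
    0.4880208, 0.4652152, 10.06244, 0.4978215,
])

COHORT_N = 46
LQRV_MEAN = 28.67
LQRV_SD = 4.22
MULTIPLE_R = 0.88

#: two-sided desirability anchors on the LQrv scale
DESIRABILITY_LOW = 22.0
DESIRABILITY_HIGH = 40.0


def derived_residual_sd() -> float:
    """Residual SD implied by the outcome SD and multiple R: σ·√(1−R²) ≈ 2.00."""
    return LQRV_SD * math.sqrt(1.0 - MULTIPLE_R**2)


def center_prediction(
    coefficients: np.ndarray | None = None,
    means: np.ndarray | None = None,
) -> float:
    """Predicted LQrv with every factor at its cohort mean (≈ 28.674)."""
    b = STUDY_COEFFICIENTS if coefficients is None else np.asarray(coefficients, float)
    m = STUDY_FACTOR_MEANS if means is None else np.asarray(means, float)
    return float(b[0] + b[1:] @ m)


# ---------------------------------------------------------------------------
# cohort frequencies emulated by the synthetic generator
# ---------------------------------------------------------------------------

#: mutant-allele frequency per biallelic / TA-repeat variant (MCS cohort).
#: MPO uses 0.337 as derived from the cohort's genotype counts
#: (the printed allele row has its labels swapped).
MUTANT_ALLELE_FREQS: dict[str, float] = {
    "MTHFR_C677T": 0.457,
    "MTHFR_A1298C": 0.228,
    "UGT1A1_28": 0.413,
    "CYP2C9_A1075T": 0.087,
    "CYP2C9_C430T": 0.196,
    "MPO_G463A": 0.337,
    "GSTP1_A313G": 0.337,
    "SOD2_C48T": 0.565,
    "CAT_C262T": 0.272,
    "OGG1_C315G": 0.196,
    "PON1_A575G": 0.304,
    "PON1_C108T": 0.478,
    "NOS3_G894T": 0.381,
}

#: frequency of the null (deleted) genotype for the presence/absence assays
DELETION_NULL_FREQS: dict[str, float] = {
    "GSTM1_DEL": 0.587,
    "GSTT1_DEL": 0.239,
}

#: star-allele frequencies for the diplotype-level genes.  CYP2C19 is the
#: cohort's printed allele distribution.  CYP2D6 allele frequencies were
#: not printed (only phenotype fractions PM/IM/EM/UM = 6.5/6.5/80.5/6.5%);
#: the defaults below were chosen once so that Hardy-Weinberg diplotypes
#: approximate that phenotype mix.
STAR_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "CYP2C19": {"*1": 0.695, "*2": 0.130, "*17": 0.175},
    "CYP2D6": {
        "*1": 0.44, "*2": 0.16, "*2A": 0.09, "*2xN": 0.03,
        "*10": 0.07, "*41": 0.04, "*4": 0.15, "*6": 0.02,
    },
}

#: prevalence of the binary anamnestic factors (events / 46)
EXPOSURE_PROBS: dict[str, float] = {
    "compounds_exposure": 24 / 46,
    "psychological_trauma": 17 / 46,
    "physical_trauma": 14 / 46,
    "previous_surgery": 14 / 46,
}

AGE_MEAN = 47.23913
AGE_SD = 10.06
FEMALE_PROB = 27 / 46
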