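"""Synthetic MCS cohorts with the statistical structure the analysis assumes.

The study's patient data were never deposited, so the generator emulates
a cohort with the published structure: genotypes drawn per variant under
Hardy–Weinberg from the cohort allele frequencies (deletion assays as
Bernoulli null-genotype draws, star-gene diplotypes as two allele draws
that are then phenotype-called), binary anamnestic events at the
published prevalences, age Gaussian (truncated to [18, 90]), and the
LQrv outcome generated from the published nine-factor linear model plus
Gaussian noise, rounded to an integer and clamped to the questionnaire
range [0, 57].  The pre-rounding latent outcome is kept alongside for
parameter-recovery tests.

Two modes:

* ``genotype`` (default) — full pipeline realism: genotypes are drawn
  and the class scores are *computed* from them, so the induced score
  distributions follow from the allele frequencies;
* ``direct-score`` — the nine regression factors are drawn directly as
  integer class scores / Bernoulli events / Gaussian age matched to the
  published factor means and SDs, for regression-focused experiments.

Independence caveats: variants are drawn independently (no linkage
between the two CYP2C9 sites) and the factors are mutually independent,
which the real cohort's factors were demonstrably not; see the methods
note for what this implies for the achievable multiple R.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import study
from .genotypes import GenotypeCall, class_scores
from .qod import (
    DEFAULT_ITEM_POLARITIES,
    Answer,
    Polarity,
    QODResponseSheet,
)
from .registry import (
    DELETION_NULL,
    DELETION_PRESENT,
    AssayKind,
    default_registry,
)
from .regression import MIN_N

AGE_BOUNDS = (18.0, 90.0)

#: score → answer, for negative statements (positive mirror-imaged)
_NS_ANSWER_FOR_POINTS = {3: Answer.AGREE, 2: Answer.PARTLY_AGREE,
                         1: Answer.PARTLY_DISAGREE, 0: Answer.DISAGREE}

#: legal integer ranges of the three class scores
CLASS_SCORE_RANGES = {"mthfr_score": (0, 4), "phase2_score": (0, 18),
                      "phase1_score": (-2, 10)}


@dataclass
class GeneratorParams:
    """Cohort-generator parameters; defaults restate the published cohort."""

    n: int = study.COHORT_N
    seed: int | None = None
    mode: str = "genotype"  # or "direct-score"
    mutant_allele_freqs: dict[str, float] = field(
        default_factory=lambda: dict(study.MUTANT_ALLELE_FREQS))
    deletion_null_freqs: dict[str, float] = field(
        default_factory=lambda: dict(study.DELETION_NULL_FREQS))
    star_allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in study.STAR_ALLELE_FREQS.items()})
    exposure_probs: dict[str, float] = field(
        default_factory=lambda: dict(study.EXPOSURE_PROBS))
    age_mean: float = study.AGE_MEAN
    age_sd: float = study.AGE_SD
    female_prob: float = study.FEMALE_PROB
    true_coefficients: np.ndarray = field(
        default_factory=lambda: study.STUDY_COEFFICIENTS.copy())
    residual_sd: float = field(default_factory=study.derived_residual_sd)
    #: direct-score mode only: target factor means and SDs
    factor_means: np.ndarray = field(
        default_factory=lambda: study.STUDY_FACTOR_MEANS.copy())
    factor_sds: np.ndarray = field(
        default_factory=lambda: study.STUDY_FACTOR_SDS.copy())

    def validate(self) -> None:
        if self.n < MIN_N:
            raise ValueError(
                f"n={self.n} too small to support the nine-predictor fit "
                f"(need ≥ {MIN_N})")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be ≥ 0")
        probs = (list(self.mutant_allele_freqs.values())
                 + list(self.deletion_null_freqs.values())
                 + list(self.exposure_probs.values())
                 + [self.female_prob])
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all frequencies/probabilities must lie in [0, 1]")
        for gene, freqs in self.star_allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{gene} allele frequencies sum to {total}, not 1")
        if self.mode not in ("genotype", "direct-score"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CohortTable:
    """Aligned synthetic-cohort tables (one row per patient)."""

    genotypes: pd.DataFrame        # long: patient_id, gene, variant_id, genotype
    anamnestic: pd.DataFrame       # patient_id, age, gender, four binary events
    factors: pd.DataFrame          # x1..x9 in canonical order, patient_id index
    lqrv: pd.Series                # integer outcome in [0, 57]
    latent_lqrv: pd.Series         # pre-rounding outcome
    qod_sheets: dict[str, QODResponseSheet] | None = None

    @property
    def n(self) -> int:
        return len(self.factors)


def _draw_biallelic(rng: np.random.Generator, pdef, q_mut: float) -> tuple[str, str]:
    dose = rng.binomial(2, q_mut)
    wt = pdef.alleles[0]
    mut = pdef.alleles[1]
    return (wt, wt) if dose == 0 else ((wt, mut) if dose == 1 else (mut, mut))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(
    params: GeneratorParams | None = None,
    seed: int | None = None,
    with_qod: bool = False,
    **overrides,
) -> CohortTable:
    """Draw a reproducible synthetic cohort.

    ``seed`` overrides ``params.seed``; keyword overrides patch individual
    parameter fields (e.g. ``n=5000, residual_sd=0.0``).
    """
    params = params or GeneratorParams()
    if overrides:
        params = replace(params, **overrides)
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    registry = default_registry()
    ids = [f"S{i + 1:04d}" for i in range(params.n)]

    # anamnestic factors: genotype mode follows the published cohort
    # prevalences; direct-score mode matches the published factor means
    # (which for psychological trauma differ from the prevalence table —
    # an inconsistency of the source summaries, kept as stated)
    if params.mode == "genotype":
        events = {name: rng.binomial(1, p, size=params.n).astype(int)
                  for name, p in params.exposure_probs.items()}
        age = _truncated_normal(rng, params.age_mean, params.age_sd,
                                *AGE_BOUNDS, size=params.n)
        gender = rng.binomial(1, params.female_prob, size=params.n).astype(int)
    else:
        means = {name: params.factor_means[study.FACTOR_NAMES.index(name)]
                 for name in study.FACTOR_NAMES}
        events = {name: rng.binomial(1, means[name], size=params.n).astype(int)
                  for name in ("compounds_exposure", "psychological_trauma",
                               "physical_trauma", "previous_surgery")}
        age = _truncated_normal(
            rng, means["age"],
            params.factor_sds[study.FACTOR_NAMES.index("age")],
            *AGE_BOUNDS, size=params.n)
        gender = rng.binomial(1, means["gender"], size=params.n).astype(int)

    geno_rows: list[dict] = []
    if params.mode == "genotype":
        score_cols = {"mthfr_score": [], "phase2_score": [], "phase1_score": []}
        for pid in ids:
            calls: dict[str, GenotypeCall] = {}
            for vid, pdef in registry.items():
                if pdef.assay_kind is AssayKind.DELETION_PRESENCE:
                    null = rng.random() < params.deletion_null_freqs[vid]
                    alleles = (DELETION_NULL if null else DELETION_PRESENT,)
                elif pdef.assay_kind is AssayKind.STAR_DIPLOTYPE:
                    freqs = params.star_allele_freqs[pdef.gene]
                    labels = list(freqs)
                    alleles = tuple(rng.choice(labels, size=2, p=list(freqs.values())))
                else:
                    alleles = _draw_biallelic(rng, pdef,
                                              params.mutant_allele_freqs[vid])
                calls[vid] = GenotypeCall(pid, vid, alleles)
                geno_rows.append({"patient_id": pid, "gene": pdef.gene,
                                  "variant_id": vid,
                                  "genotype": "/".join(alleles)})
            cs = class_scores(calls, registry)
            score_cols["mthfr_score"].append(cs.mthfr_score)
            score_cols["phase2_score"].append(cs.phase2_score)
            score_cols["phase1_score"].append(cs.phase1_score)
        scores = {k: np.array(v) for k, v in score_cols.items()}
    else:  # direct-score: integer class scores matched to the target moments
        scores = {}
        for name in ("mthfr_score", "phase2_score", "phase1_score"):
            j = study.FACTOR_NAMES.index(name)
            lo, hi = CLASS_SCORE_RANGES[name]
            draw = np.rint(rng.normal(params.factor_means[j],
                                      params.factor_sds[j], size=params.n))
            scores[name] = np.clip(draw, lo, hi).astype(int)

    factors = pd.DataFrame({
        "mthfr_score": scores["mthfr_score"],
        "phase2_score": scores["phase2_score"],
        "phase1_score": scores["phase1_score"],
        "compounds_exposure": events["compounds_exposure"],
        "psychological_trauma": events["psychological_trauma"],
        "physical_trauma": events["physical_trauma"],
        "previous_surgery": events["previous_surgery"],
        "age": age,
        "gender": gender,
    }, index=pd.Index(ids, name="patient_id"))[list(study.FACTOR_NAMES)]

    b = np.asarray(params.true_coefficients, float)
    latent = b[0] + factors.to_numpy(float) @ b[1:]
    if params.residual_sd > 0:
        latent = latent + rng.normal(0.0, params.residual_sd, size=params.n)
    latent = pd.Series(latent, index=factors.index, name="latent_lqrv")
    lqrv = latent.round().clip(0, 57).astype(int).rename("lqrv")

    anamnestic = pd.DataFrame({
        "patient_id": ids, "age": age, "gender": gender,
        **{k: events[k] for k in ("compounds_exposure", "psychological_trauma",
                                  "physical_trauma", "previous_surgery")},
    })

    sheets = None
    if with_qod:
        sheets = {pid: qod_sheet_from_lqrv(int(lqrv.loc[pid]), rng=rng,
                                           patient_id=pid)
                  for pid in ids}

    return CohortTable(pd.DataFrame(geno_rows), anamnestic, factors,
                       lqrv, latent, sheets)


def qod_sheet_from_lqrv(
    target: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    patient_id: str = "synthetic",
) -> QODResponseSheet:
    """Random complete questionnaire sheet scoring exactly ``target`` points.

    Inverse of the questionnaire scoring: ``target`` points are
    distributed uniformly at random over the 19 items (3 points max
    each), then translated back to Likert answers respecting each item's
    polarity.
    """
    if not 0 <= target <= 57:
        raise ValueError(f"target LQrv {target} outside [0, 57]")
    if rng is None:
        rng = np.random.default_rng(seed)
    items = sorted(DEFAULT_ITEM_POLARITIES)
    points = {i: 0 for i in items}
    remaining = int(target)
    while remaining > 0:
        open_items = [i for i in items if points[i] < 3]
        points[rng.choice(open_items)] += 1
        remaining -= 1
    responses = []
    for i in items:
        pol = DEFAULT_ITEM_POLARITIES[i]
        pts = points[i] if pol is Polarity.NS else 3 - points[i]
        responses.append((i, pol, _NS_ANSWER_FOR_POINTS[pts]))
    return QODResponseSheet(patient_id, tuple(responses))
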