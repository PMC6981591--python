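"""End-to-end orchestration: simulate → score → analyze → profile.

``run_full`` executes questionnaire scoring, class scoring, frequency
tables, the nine-factor regression (or a "skip-fit" pass with a supplied
coefficient vector), the Pareto data, the desirability profile and the
cut-off search as one reproducible run, writing the artifact bundle plus
a JSON run-report.  Skip-fit mode exists because the study's headline
artifacts (profile grid, cut-offs) are pure functions of the published
coefficient vector and factor statistics, hence reproducible without the
original cohort; fit and skip-fit share all downstream code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, study
from .desirability import (
    DesirabilitySpec,
    ProfileContext,
    all_profiles,
    find_cutoffs,
)
from .frequencies import genotype_frequencies
from .genotypes import GenotypeCall, call_metabolizer, class_scores
from .io import write_results
from .qod import compute_lqrv
from .registry import AssayKind, default_registry
from .regression import (
    MULTIPLICITY_CAVEAT,
    fit_ols,
    model_diagnostics,
    pareto_data,
)
from .simulate import CohortTable, GeneratorParams, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int | None = None
    out_dir: str | Path | None = None
    alpha: float = 0.05
    desirability: DesirabilitySpec = field(default_factory=DesirabilitySpec)
    cutoff_target: float | None = None  # default: the center prediction
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    #: length-10 coefficient vector → skip the fit and profile these
    skip_fit_coefficients: np.ndarray | None = None
    #: with skip-fit: factor means/SDs to profile on (default: published)
    skip_fit_means: np.ndarray | None = None
    skip_fit_sds: np.ndarray | None = None


def _factor_table_from_cohort(cohort: CohortTable) -> pd.DataFrame:
    return cohort.factors


def score_cohort_qod(cohort: CohortTable) -> pd.Series:
    """LQrv per patient from attached questionnaire sheets (if present)."""
    if cohort.qod_sheets is None:
        raise ValueError("cohort has no questionnaire sheets attached")
    return pd.Series({pid: compute_lqrv(sheet).lqrv
                      for pid, sheet in cohort.qod_sheets.items()},
                     name="lqrv")


def frequency_report(cohort: CohortTable) -> pd.DataFrame:
    """Genotype/allele frequency table across the whole registry."""
    registry = default_registry()
    calls = [GenotypeCall(r.patient_id, r.variant_id,
                          tuple(r.genotype.split("/")))
             for r in cohort.genotypes.itertuples()]
    frames = [genotype_frequencies(calls, pdef).to_frame()
              for pdef in registry.values()]
    return pd.concat(frames, ignore_index=True)


def run_full(config: RunConfig | None = None) -> dict:
    """Run the whole pipeline on a (simulated) cohort; return the run-report.

    The report dict carries the seed, package version, fit summary,
    profile/cut-off artifacts and the multiplicity caveat.  When
    ``config.out_dir`` is set the artifact bundle is also written there
    (regression.csv, pareto.csv, profile.csv, frequencies.csv,
    cutoffs.csv, lqrv.csv, run_report.json).
    """
    config = config or RunConfig()
    cohort = generate_cohort(config.generator, seed=config.seed, with_qod=True)

    # questionnaire scoring must agree with the generated outcome
    qod_lqrv = score_cohort_qod(cohort)
    if not (qod_lqrv.sort_index() == cohort.lqrv.sort_index()).all():
        raise RuntimeError("questionnaire scoring does not reproduce the "
                           "generated LQrv")  # pragma: no cover

    results: dict[str, object] = {}
    if not cohort.genotypes.empty:
        results["frequencies"] = frequency_report(cohort)

    skip_fit = config.skip_fit_coefficients is not None
    if skip_fit:
        ctx = ProfileContext(
            np.asarray(config.skip_fit_coefficients, float),
            study.STUDY_FACTOR_MEANS if config.skip_fit_means is None
            else np.asarray(config.skip_fit_means, float),
            study.STUDY_FACTOR_SDS if config.skip_fit_sds is None
            else np.asarray(config.skip_fit_sds, float),
        )
        fit_summary: dict = {"mode": "skip-fit"}
    else:
        fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
        design = np.column_stack([np.ones(cohort.n), cohort.factors.to_numpy(float)])
        fitted = design @ fit.coefficients
        resid = cohort.lqrv.to_numpy(float) - fitted
        results["regression"] = fit.to_frame()
        results["pareto"] = pareto_data(fit, config.alpha).to_frame()
        fit_summary = {
            "mode": "fit",
            "n": fit.n,
            "multiple_r": fit.multiple_r,
            "r_squared": fit.r_squared,
            "f_value": fit.f_value,
            "model_p": fit.model_p,
            "df_resid": fit.df_resid,
            "diagnostics": model_diagnostics(fit, resid, fitted),
        }
        ctx = ProfileContext.from_fit(fit)

    center = config.desirability.resolved_center(ctx.center_prediction)
    results["profile"] = all_profiles(ctx, config.desirability)
    target = config.cutoff_target if config.cutoff_target is not None else center
    results["cutoffs"] = find_cutoffs(ctx, target, config.desirability)
    results["lqrv"] = cohort.lqrv.rename_axis("patient_id").reset_index()

    report = {
        "package_version": __version__,
        "seed": config.seed if config.seed is not None else config.generator.seed,
        "n": cohort.n,
        "mode": fit_summary["mode"],
        "fit": fit_summary,
        "center_prediction": center,
        "cutoff_target": target,
        "desirability_low": config.desirability.low,
        "desirability_high": config.desirability.high,
        "caveat": MULTIPLICITY_CAVEAT,
        "artifacts": sorted(results),
    }
    results["run_report"] = report

    if config.out_dir is not None:
        written = write_results(results, config.out_dir)
        logger.info("wrote %d artifacts to %s", len(written), config.out_dir)
    return report
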