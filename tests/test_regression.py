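"""Nine-factor OLS: oracle equivalence, report statistics, Pareto data."""

import numpy as np
import pandas as pd
import pytest

from mcsqol import (
    ParetoData,
    fit_ols,
    generate_cohort,
    model_diagnostics,
    pareto_data,
    predict_lqrv,
    study,
)
from mcsqol.regression import RegressionFit

from conftest import ols_normal_equations


def _random_cohort(rng, n):
    cohort = generate_cohort(seed=int(rng.integers(2**31)), n=n,
                             mode="direct-score")
    return cohort.factors, cohort.latent_lqrv.to_numpy()


def test_noise_free_recovery_of_study_coefficients():
    """Outcome generated exactly from the published linear model → exact refit."""
    cohort = generate_cohort(seed=11, n=400, residual_sd=0.0, mode="direct-score")
    fit = fit_ols(cohort.factors, cohort.latent_lqrv.to_numpy())
    np.testing.assert_allclose(fit.coefficients, study.STUDY_COEFFICIENTS,
                               atol=1e-8)
    assert fit.multiple_r == pytest.approx(1.0, abs=1e-9)


def test_matches_normal_equations_oracle():
    """Coefficients agree with an explicit (XᵀX)⁻¹Xᵀy solve to 1e-9."""
    rng = np.random.default_rng(7)
    for n in (15, 46, 200):
        X, y = _random_cohort(rng, n)
        fit = fit_ols(X, y)
        expected = ols_normal_equations(X.to_numpy(float), y)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-9 * max(
            1.0, np.abs(expected).max()))


def test_prediction_at_means_equals_mean_outcome():
    cohort = generate_cohort(seed=3, n=46)
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    at_means = predict_lqrv(fit, fit.x_means)
    assert at_means == pytest.approx(fit.y_mean, abs=1e-9)


def test_standardized_beta_roundtrip():
    """b_j recovered from β_j·sd(y)/sd(x_j) to 1e-9."""
    cohort = generate_cohort(seed=5, n=100)
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    recovered = fit.std_betas * fit.y_sd / fit.x_sds
    np.testing.assert_allclose(recovered, fit.coefficients[1:], atol=1e-9)


def test_partial_correlation_definition():
    cohort = generate_cohort(seed=6, n=80)
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    t = fit.t_values[1:]
    np.testing.assert_allclose(fit.partial_corr,
                               t / np.sqrt(t**2 + fit.df_resid), atol=1e-12)


def test_basic_fit_invariants():
    cohort = generate_cohort(seed=8, n=46)
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    assert fit.df_resid == 46 - 10
    np.testing.assert_allclose(fit.t_values,
                               fit.coefficients / fit.std_errors, atol=1e-10)
    assert 0.0 <= fit.r_squared <= 1.0
    assert "no correction for multiple comparisons" in fit.caveat
    frame = fit.to_frame()
    assert len(frame) == 10  # intercept + 9 factors


def test_predict_with_study_vector():
    """Intercept-only prediction: all factors at zero → 18.63568."""
    assert predict_lqrv(study.STUDY_COEFFICIENTS, np.zeros(9)) == pytest.approx(
        18.63568)
    with pytest.raises(ValueError, match="length"):
        predict_lqrv(study.STUDY_COEFFICIENTS, np.zeros(5))


@pytest.mark.parametrize("breaker,match", [
    ("constant_outcome", "constant outcome"),
    ("constant_column", "rank-deficient"),
    ("too_small", "too small"),
    ("missing", "missing values"),
])
def test_degenerate_inputs_rejected(breaker, match):
    cohort = generate_cohort(seed=9, n=46)
    X = cohort.factors.copy()
    y = cohort.lqrv.to_numpy(float)
    if breaker == "constant_outcome":
        y = np.full(46, 30.0)
    elif breaker == "constant_column":
        X["previous_surgery"] = 1
    elif breaker == "too_small":
        X, y = X.iloc[:5], y[:5]
    elif breaker == "missing":
        X = X.astype(float)
        X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match=match):
        fit_ols(X, y)


# ---------------------------------------------------------------------------
# Pareto data
# ---------------------------------------------------------------------------

def _fit_with_t_values(t_values, df=36):
    """Minimal RegressionFit stub carrying published t-values."""
    t = np.array([t_values["intercept"]] + [t_values[f] for f in study.FACTOR_NAMES])
    k = t.size
    z = np.zeros(k)
    return RegressionFit(
        factor_names=study.FACTOR_NAMES, coefficients=z, std_errors=z,
        t_values=t, p_values=z, conf_low=z, conf_high=z,
        std_betas=z[1:], partial_corr=z[1:], multiple_r=0.88, r_squared=0.77,
        f_value=0.0, model_p=0.0, df_resid=df, n=df + k,
        x_means=z[1:], x_sds=z[1:], y_mean=0.0, y_sd=1.0)


def test_pareto_order_of_study_t_values(table3_t_values):
    """|t| ranking: phase I > compounds > surgery > phase II > MTHFR
    > psychological > age > gender > physical."""
    data = pareto_data(_fit_with_t_values(table3_t_values))
    assert list(data.factor_names) == [
        "phase1_score", "compounds_exposure", "previous_surgery",
        "phase2_score", "mthfr_score", "psychological_trauma",
        "age", "gender", "physical_trauma"]
    assert np.all(np.diff(data.abs_t) <= 0)
    # exactly the four leading factors clear the cut-off
    assert data.to_frame()["significant"].tolist() == [True] * 4 + [False] * 5


def test_pareto_critical_t_df36(table3_t_values):
    """Two-sided 5% critical t with 36 df ≈ 2.0281 (numeric-integration oracle).

    The oracle inverts the CDF obtained by trapezoidal integration of the
    t density, independently of the library quantile function.
    """
    from math import lgamma, exp

    df = 36

    def t_pdf(x):
        c = exp(lgamma((df + 1) / 2) - lgamma(df / 2)) / np.sqrt(df * np.pi)
        return c * (1 + x**2 / df) ** (-(df + 1) / 2)

    xs = np.linspace(0, 12, 240001)
    cdf_half = np.cumsum((t_pdf(xs[:-1]) + t_pdf(xs[1:])) / 2 * np.diff(xs))
    target = 0.475  # P(0 < T < t) for the two-sided 5% point
    t_crit_oracle = xs[1:][np.searchsorted(cdf_half, target)]
    assert t_crit_oracle == pytest.approx(2.0281, abs=2e-4)

    data = pareto_data(_fit_with_t_values(table3_t_values), alpha=0.05)
    assert data.critical_t == pytest.approx(t_crit_oracle, abs=1e-4)


def test_pareto_single_factor():
    fit = _fit_with_t_values({"intercept": 1.0, **{f: 0.0 for f in study.FACTOR_NAMES},
                              "phase1_score": 2.5})
    data = pareto_data(fit)
    assert data.factor_names[0] == "phase1_score"
    assert isinstance(data, ParetoData)


# ---------------------------------------------------------------------------
# diagnostics (advisory)
# ---------------------------------------------------------------------------

def test_diagnostics_gaussian_vs_skewed():
    """Normality check accepts Gaussian and rejects log-normal residuals."""
    rng = np.random.default_rng(42)
    cohort = generate_cohort(seed=10, n=500, mode="direct-score")
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    fitted = np.full(500, 28.0)
    accept = reject = 0
    for _ in range(20):
        gauss = model_diagnostics(fit, rng.normal(0, 2, 500), fitted)
        skew = model_diagnostics(fit, np.exp(rng.normal(0, 1, 500)), fitted)
        accept += gauss["normality_p"] > 0.05
        reject += skew["normality_p"] < 0.05
    assert accept >= 18  # ≥90 % of Gaussian replicates pass
    assert reject >= 18  # ≥90 % of skewed replicates fail


def test_diagnostics_skipped_for_tiny_n():
    cohort = generate_cohort(seed=10, n=46)
    fit = fit_ols(cohort.factors, cohort.lqrv.to_numpy())
    out = model_diagnostics(fit, np.zeros(5), np.zeros(5))
    assert out["skipped"] is True
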