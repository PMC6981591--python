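"""Nine-predictor ordinary-least-squares model of the LQrv outcome.

The model is

    X = b0 + b1·x1 + … + b9·x9

with x1..x9 = (MTHFR class score, phase II class score, phase I class
score, compounds exposure, psychological trauma, physical trauma,
previous surgery, age, gender).  Besides the usual per-coefficient
statistics (SE, t, p, 95% CI with n−10 residual df) the fit reports
standardized coefficients β_j = b_j·sd(x_j)/sd(y) (n−1 sample SDs) and
partial correlations r_j = t_j/√(t_j²+df), plus multiple R, R², F and the
model p-value.  No multiple-comparison correction is applied; reports
carry an explicit caveat to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .study import FACTOR_NAMES

MIN_N = 12  # need at least a couple of residual df beyond the 10 parameters

#: caveat attached to every regression report
MULTIPLICITY_CAVEAT = (
    "Exploratory model: no correction for multiple comparisons is applied "
    "to the per-factor p-values."
)


@dataclass
class RegressionFit:
    """Fitted nine-factor OLS model and its report statistics.

    ``coefficients`` is the length-10 vector (intercept first, then the
    slopes in the canonical x1..x9 order); the per-coefficient arrays are
    aligned with it.
    """

    factor_names: tuple[str, ...]
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    conf_low: np.ndarray
    conf_high: np.ndarray
    std_betas: np.ndarray        # slopes only, aligned with factor_names
    partial_corr: np.ndarray     # slopes only
    multiple_r: float
    r_squared: float
    f_value: float
    model_p: float
    df_resid: int
    n: int
    x_means: np.ndarray
    x_sds: np.ndarray            # n−1 sample SDs
    y_mean: float
    y_sd: float
    caveat: str = MULTIPLICITY_CAVEAT

    def to_frame(self) -> pd.DataFrame:
        """Per-coefficient report table (intercept + 9 factors)."""
        rows = ("intercept",) + tuple(self.factor_names)
        return pd.DataFrame({
            "term": rows,
            "coefficient": self.coefficients,
            "std_error": self.std_errors,
            "t": self.t_values,
            "p_value": self.p_values,
            "conf_low_95": self.conf_low,
            "conf_high_95": self.conf_high,
            "std_beta": np.concatenate([[np.nan], self.std_betas]),
            "partial_corr": np.concatenate([[np.nan], self.partial_corr]),
        })


def _as_design(factors: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(factors, pd.DataFrame):
        missing = [c for c in FACTOR_NAMES if c not in factors.columns]
        if missing:
            raise ValueError(f"factor table lacks columns {missing}")
        return factors.loc[:, list(FACTOR_NAMES)].to_numpy(float), FACTOR_NAMES
    arr = np.asarray(factors, float)
    if arr.ndim != 2:
        raise ValueError("factors must be a 2-D array or DataFrame")
    names = FACTOR_NAMES if arr.shape[1] == len(FACTOR_NAMES) else tuple(
        f"x{i+1}" for i in range(arr.shape[1]))
    return arr, names


def fit_ols(factors: pd.DataFrame | np.ndarray, lqrv) -> RegressionFit:
    """Fit the LQrv ~ x1..x9 model by ordinary least squares.

    Raises ``ValueError`` for n below :data:`MIN_N`, missing values,
    a rank-deficient design (collinear or constant columns are named),
    or a constant outcome (R undefined).
    """
    X, names = _as_design(factors)
    y = np.asarray(lqrv, float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"outcome length {y.shape} does not match n={n}")
    if n < max(MIN_N, p + 3):
        raise ValueError(f"n={n} too small for a {p}-predictor fit (need ≥ {max(MIN_N, p + 3)})")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in design or outcome")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        sds = X.std(axis=0, ddof=1)
        constant = [names[j] for j in range(p) if sds[j] == 0]
        detail = f"constant columns: {constant}" if constant else "collinear columns"
        raise ValueError(f"rank-deficient design (rank {rank} < {p + 1}); {detail}")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: multiple R is undefined")

    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    x_sds = X.std(axis=0, ddof=1)
    y_sd = y.std(ddof=1)
    t_slopes = res.tvalues[1:]
    df = int(res.df_resid)
    return RegressionFit(
        factor_names=names,
        coefficients=res.params.copy(),
        std_errors=res.bse.copy(),
        t_values=res.tvalues.copy(),
        p_values=res.pvalues.copy(),
        conf_low=ci[:, 0].copy(),
        conf_high=ci[:, 1].copy(),
        std_betas=res.params[1:] * x_sds / y_sd,
        partial_corr=t_slopes / np.sqrt(t_slopes**2 + df),
        multiple_r=float(np.sqrt(res.rsquared)),
        r_squared=float(res.rsquared),
        f_value=float(res.fvalue),
        model_p=float(res.f_pvalue),
        df_resid=df,
        n=n,
        x_means=X.mean(axis=0),
        x_sds=x_sds,
        y_mean=float(y.mean()),
        y_sd=float(y_sd),
    )


def predict_lqrv(coefficients: np.ndarray | RegressionFit, x) -> float:
    """Evaluate b0 + Σ b_j·x_j for one factor vector of length 9."""
    b = coefficients.coefficients if isinstance(coefficients, RegressionFit) \
        else np.asarray(coefficients, float)
    xv = np.asarray(x, float)
    if b.shape != (xv.size + 1,):
        raise ValueError(
            f"coefficient vector of length {b.size} does not match "
            f"{xv.size} factors (+ intercept)")
    return float(b[0] + b[1:] @ xv.ravel())


@dataclass
class ParetoData:
    """Factors ordered by |t| with the two-sided significance cut-off."""

    factor_names: tuple[str, ...]
    abs_t: np.ndarray
    t_values: np.ndarray
    critical_t: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factor_names,
            "t": self.t_values,
            "abs_t": self.abs_t,
            "significant": self.abs_t > self.critical_t,
        })


def pareto_data(fit: RegressionFit, alpha: float = 0.05) -> ParetoData:
    """Slope |t| values sorted descending, with the critical t at ``alpha``."""
    t = fit.t_values[1:]
    order = np.argsort(-np.abs(t), kind="stable")
    return ParetoData(
        factor_names=tuple(fit.factor_names[j] for j in order),
        abs_t=np.abs(t)[order],
        t_values=t[order],
        critical_t=float(st.t.ppf(1 - alpha / 2, fit.df_resid)),
        alpha=alpha,
    )


def model_diagnostics(fit: RegressionFit, residuals: np.ndarray | None = None,
                      fitted: np.ndarray | None = None) -> dict:
    """Advisory residual checks: D'Agostino K² normality and Levene's test.

    Homoscedasticity is assessed by splitting the residuals at the median
    fitted value and comparing spread between the two halves.  With n < 8
    the checks are skipped (returned with ``skipped=True``); they never
    gate the pipeline.
    """
    if residuals is None or fitted is None:
        raise ValueError("pass the residual and fitted-value arrays")
    residuals = np.asarray(residuals, float)
    fitted = np.asarray(fitted, float)
    if residuals.size < 8:
        return {"skipped": True,
                "reason": f"n={residuals.size} < 8: residual checks not meaningful"}
    k2, norm_p = st.normaltest(residuals)
    lo = residuals[fitted <= np.median(fitted)]
    hi = residuals[fitted > np.median(fitted)]
    if min(lo.size, hi.size) < 2:
        lev_stat, lev_p = np.nan, np.nan
    else:
        lev_stat, lev_p = st.levene(lo, hi)
    return {
        "skipped": False,
        "normality_k2": float(k2),
        "normality_p": float(norm_p),
        "levene_stat": float(lev_stat),
        "levene_p": float(lev_p),
    }
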