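"""Two-sided desirability profiling of the predicted LQrv.

The response is mapped to a partial desirability d ∈ [0, 1] by a
piecewise-linear transform through three anchors: (low, 0),
(center, 0.5), (high, 1), clamped outside [low, high].  Defaults are
low = 22, high = 40, center = the cohort mean prediction (≈ 28.67).
Because the study is framed around *risk identification*, higher LQrv
(worse olfactory quality of life) maps to higher desirability — d reads
as "how fully the factor setting drives the response toward the
high-impairment end of the band", not as clinical benefit.

Each factor is profiled on a five-level grid mean + k·SD, k ∈ −2..2
(sample SDs, n−1 denominator), holding every other factor at its mean;
binary factors are profiled on the same continuous grid, so levels
outside {0, 1} are intentional.  Partial desirabilities combine into a
global desirability by geometric mean.  Cut-off search inverts the
single-factor linear prediction in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import study
from .regression import RegressionFit, predict_lqrv

GRID_KS: tuple[int, ...] = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class DesirabilitySpec:
    """Anchors of the two-sided transform: d(low)=0, d(center)=0.5, d(high)=1."""

    low: float = study.DESIRABILITY_LOW
    high: float = study.DESIRABILITY_HIGH
    center: float | None = None  # default: cohort mean prediction

    def resolved_center(self, default: float) -> float:
        return default if self.center is None else self.center

    def validate(self, center: float) -> None:
        if not (self.low < center < self.high):
            raise ValueError(
                f"desirability anchors must satisfy low < center < high, "
                f"got {self.low} / {center} / {self.high}")


def desirability(y: float, spec: DesirabilitySpec, center: float | None = None) -> float:
    """Partial desirability of a predicted LQrv value.

    ``center`` overrides/resolves the spec's center anchor (it usually
    comes from the fitted model's mean prediction).
    """
    c = spec.resolved_center(center) if center is not None else spec.center
    if c is None:
        raise ValueError("no center anchor: pass center= or set spec.center")
    spec.validate(c)
    if y <= spec.low:
        return 0.0
    if y >= spec.high:
        return 1.0
    if y <= c:
        return 0.5 * (y - spec.low) / (c - spec.low)
    return 0.5 + 0.5 * (y - c) / (spec.high - c)


@dataclass
class ProfileContext:
    """Coefficients + cohort factor statistics shared by profile/cut-off runs.

    ``from_fit`` builds the context from a fitted model; the plain
    constructor supports "skip-fit" use with a published coefficient
    vector and factor means/SDs, which is how the study's profile tables
    are reproduced without the original cohort.
    """

    coefficients: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    factor_names: tuple[str, ...] = study.FACTOR_NAMES

    @classmethod
    def from_fit(cls, fit: RegressionFit) -> "ProfileContext":
        return cls(fit.coefficients, fit.x_means, fit.x_sds, fit.factor_names)

    @classmethod
    def from_study(cls) -> "ProfileContext":
        return cls(study.STUDY_COEFFICIENTS.copy(), study.STUDY_FACTOR_MEANS.copy(),
                   study.STUDY_FACTOR_SDS.copy())

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        p = self.means.size
        if self.coefficients.size != p + 1 or self.sds.size != p:
            raise ValueError("coefficients must be length p+1, means/sds length p")

    @property
    def center_prediction(self) -> float:
        return predict_lqrv(self.coefficients, self.means)

    def index(self, factor: int | str) -> int:
        if isinstance(factor, str):
            return self.factor_names.index(factor)
        return int(factor)

    def predict_at(self, factor: int | str, level: float) -> float:
        """Prediction with one factor at ``level`` and the rest at their means."""
        x = self.means.copy()
        x[self.index(factor)] = level
        return predict_lqrv(self.coefficients, x)


@dataclass
class DesirabilityProfile:
    factor_name: str
    levels: np.ndarray
    predicted: np.ndarray
    partial_d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factor_name,
            "level": self.levels,
            "predicted_lqrv": self.predicted,
            "desirability": self.partial_d,
        })


def factor_profile(
    ctx: ProfileContext,
    factor: int | str,
    spec: DesirabilitySpec | None = None,
    ks: tuple[int, ...] = GRID_KS,
) -> DesirabilityProfile:
    """Five-level desirability profile of one factor (mean ± k·SD grid)."""
    spec = spec or DesirabilitySpec()
    j = ctx.index(factor)
    center = spec.resolved_center(ctx.center_prediction)
    sd = ctx.sds[j]
    levels = np.array([ctx.means[j] + k * sd for k in ks])
    predicted = np.array([ctx.predict_at(j, lev) for lev in levels])
    d = np.array([desirability(p, spec, center) for p in predicted])
    return DesirabilityProfile(ctx.factor_names[j], levels, predicted, d)


def all_profiles(
    ctx: ProfileContext,
    spec: DesirabilitySpec | None = None,
    ks: tuple[int, ...] = GRID_KS,
) -> pd.DataFrame:
    """Stacked profile table for every factor (9 factors × 5 levels)."""
    frames = [factor_profile(ctx, j, spec, ks).to_frame()
              for j in range(len(ctx.factor_names))]
    return pd.concat(frames, ignore_index=True)


def global_desirability(d_values) -> float:
    """Geometric mean of partial desirabilities; 0 annihilates."""
    d = np.asarray(list(d_values), float)
    if d.size == 0:
        raise ValueError("no partial desirabilities given")
    if ((d < 0) | (d > 1)).any():
        raise ValueError("partial desirabilities must lie in [0, 1]")
    if (d == 0).any():
        return 0.0
    return float(np.exp(np.log(d).mean()))


def find_cutoffs(
    ctx: ProfileContext,
    target: float,
    spec: DesirabilitySpec | None = None,
    k_range: float = 2.0,
) -> pd.DataFrame:
    """Per-factor minimal level at which the prediction reaches ``target``.

    For each positive-coefficient factor, solves
    center + b_j·(level − mean_j) = target for ``level`` (all other
    factors at their means).  Levels outside the mean ± ``k_range``·SD
    grid are flagged unreachable.  ``target`` must lie within the
    desirability band [low, high].
    """
    spec = spec or DesirabilitySpec()
    center = spec.resolved_center(ctx.center_prediction)
    spec.validate(center)
    if not (spec.low <= target <= spec.high):
        raise ValueError(f"target {target} outside the band [{spec.low}, {spec.high}]")
    rows = []
    for j, name in enumerate(ctx.factor_names):
        b = ctx.coefficients[j + 1]
        if b <= 0:
            continue
        level = ctx.means[j] + (target - center) / b
        lo = ctx.means[j] - k_range * ctx.sds[j]
        hi = ctx.means[j] + k_range * ctx.sds[j]
        rows.append({
            "factor": name,
            "cutoff_level": level,
            "reachable": bool(lo <= level <= hi),
        })
    return pd.DataFrame(rows)
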