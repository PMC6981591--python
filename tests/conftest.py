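"""Shared fixtures: published reference tables of the modelled study."""

import numpy as np
import pytest

# Published desirability-profile grid: per factor, five
# (level, predicted LQrv, partial desirability) rows (mean + k·SD levels,
# k = -2..2) under the published coefficient vector and anchors 22/40.
TABLE4_ROWS = {
    "mthfr_score": [
        (-0.363323, 27.18730, 0.388626),
        (0.4813819, 27.93061, 0.444314),
        (1.326087, 28.67391, 0.500001),
        (2.170792, 29.41722, 0.532814),
        (3.015497, 30.16052, 0.565628),
    ],
    "phase2_score": [
        (0.8952978, 26.68338, 0.350873),
        (3.371562, 27.67865, 0.425437),
        (5.847826, 28.67391, 0.500001),
        (8.324090, 29.66918, 0.543937),
        (10.80035, 30.66444, 0.587874),
    ],
    "phase1_score": [
        (-0.721111, 26.23453, 0.317246),
        (0.3894446, 27.45422, 0.408623),
        (1.500000, 28.67391, 0.500001),
        (2.610555, 29.89360, 0.553845),
        (3.721111, 31.11329, 0.607689),
    ],
    "compounds_exposure": [
        (-0.488355, 26.11192, 0.308060),
        (0.0166921, 27.39292, 0.404031),
        (0.5217391, 28.67391, 0.500001),
        (1.026786, 29.95491, 0.556551),
        (1.531833, 31.23590, 0.613102),
    ],
    "psychological_trauma": [
        (-0.488355, 27.40518, 0.404949),
        (0.0166921, 28.03955, 0.452475),
        (0.5217391, 28.67391, 0.500001),
        (1.026786, 29.30828, 0.528005),
        (1.531833, 29.94264, 0.556010),
    ],
    "physical_trauma": [
        (-0.606476, 28.94936, 0.512160),
        (-0.118456, 28.81164, 0.506080),
        (0.3695652, 28.67391, 0.500001),
        (0.8575860, 28.53619, 0.489683),
        (1.345607, 28.39847, 0.479365),
    ],
    "previous_surgery": [
        (-0.626082, 26.91147, 0.367961),
        (-0.160867, 27.79269, 0.433981),
        (0.3043478, 28.67391, 0.500001),
        (0.7695630, 29.55514, 0.538903),
        (1.234778, 30.43636, 0.577805),
    ],
    "age": [
        (27.11425, 27.84545, 0.437933),
        (37.17669, 28.25968, 0.468967),
        (47.23913, 28.67391, 0.500001),
        (57.30157, 29.08815, 0.518287),
        (67.36401, 29.50238, 0.536574),
    ],
    "gender": [
        (-0.408686, 27.86305, 0.439252),
        (0.0891352, 28.26848, 0.469627),
        (0.5869565, 28.67391, 0.500001),
        (1.084778, 29.07934, 0.517899),
        (1.582599, 29.48477, 0.535797),
    ],
}

# Published regression t-values in the canonical x1..x9 factor order
# (intercept first), n = 46 → 36 residual df.
TABLE3_T_VALUES = {
    "intercept": 9.541631,
    "mthfr_score": 1.938130,
    "phase2_score": 2.305473,
    "phase1_score": 3.466581,
    "compounds_exposure": 2.596462,
    "psychological_trauma": 1.256353,
    "physical_trauma": -0.296230,
    "previous_surgery": 2.330064,
    "age": 1.190050,
    "gender": 1.047519,
}


@pytest.fixture(scope="session")
def table4_rows():
    return TABLE4_ROWS


@pytest.fixture(scope="session")
def table3_t_values():
    return TABLE3_T_VALUES


@pytest.fixture(scope="session")
def study_ctx():
    from mcsqol import ProfileContext

    return ProfileContext.from_study()


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: explicit (XᵀX)⁻¹Xᵀy with an intercept column."""
    D = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)
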