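"""Two-stage regression calibration of the gradient-walking model, plus metrics.

Stage 1 fits the flat-and-uphill branch (incline >= 0) by ordinary least
squares of the measured net power on the kinetic and potential regressors
with an intercept, giving gamma, b0 and P0.  Stage 2 freezes those three
and fits the downhill quadratic gain b1 alone on the flat-and-downhill
records (incline <= 0): with residual r = P - gamma P_K - b0 P_U - P0 and
u = P_U^2 / P0, the least-squares solution is the closed form
b1 = sum(r u) / sum(u^2).  Flat records have u = 0 and carry no weight in
stage 2, so including them is harmless.

Also provided: RMSD and absolute percent error (the evaluation metrics),
adjusted R^2, and the cadence regression of (step frequency x height)
against walking speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import (
    CoefficientSet,
    DEFAULT_CONSTANTS,
    InvalidInputError,
    Sex,
)

__all__ = [
    "TrialRecord",
    "FitResult",
    "SingularDesignError",
    "compute_regressors",
    "stage1_fit",
    "stage2_fit",
    "fit_by_gender",
    "predict_trials",
    "rmsd",
    "percent_error",
    "cadence_regression",
    "adjusted_r2",
    "read_trials_csv",
    "write_trials_csv",
]

logger = logging.getLogger(__name__)

TRIALS_COLUMNS = [
    "subject_id",
    "sex",
    "mass_kg",
    "height_m",
    "speed_mps",
    "incline_deg",
    "step_freq_hz",
    "p_measured_kcal_s",
]


class SingularDesignError(InvalidInputError):
    """Regression design matrix is rank deficient."""


@dataclass(frozen=True)
class TrialRecord:
    """One participant x condition session with derived regressors (kcal/s)."""

    subject_id: str
    sex: Sex
    mass_kg: float
    speed_mps: float
    incline_deg: float
    step_freq_hz: float
    p_k_kcal_s: float
    p_u_kcal_s: float
    p_measured_kcal_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.p_k_kcal_s < 0:
            raise InvalidInputError("p_k must be >= 0")
        if self.p_u_kcal_s * self.incline_deg < 0:
            raise InvalidInputError("sign of p_u must match sign of incline")


@dataclass(frozen=True)
class FitResult:
    """Per-gender calibration output."""

    coeffs: CoefficientSet
    adj_r2_stage1: float
    rmsd_kcal_s: float
    n_stage1: int
    n_stage2: int


def compute_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Add kinetic and potential power columns (kcal/s) to a trials table."""
    missing = [c for c in TRIALS_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidInputError(f"trials table missing columns {missing}")
    out = trials.copy()
    kj = DEFAULT_CONSTANTS.kcal_joules
    out["p_k_kcal_s"] = (
        2.0
        * out["mass_kg"]
        * out["speed_mps"] ** 2
        * out["step_freq_hz"]
        / kj
    )
    out["p_u_kcal_s"] = (
        out["mass_kg"]
        * DEFAULT_CONSTANTS.g
        * out["speed_mps"]
        * np.sin(np.radians(out["incline_deg"]))
        / kj
    )
    return out


def stage1_fit(trials: pd.DataFrame) -> tuple[float, float, float, float]:
    """OLS of measured power on [p_k, p_u, 1] over incline >= 0 records.

    Returns ``(gamma, b0, p0, adj_r2)``.
    """
    sub = trials[trials["incline_deg"] >= 0]
    if len(sub) < 3:
        raise InvalidInputError(
            f"stage 1 needs >= 3 flat/uphill records, got {len(sub)}"
        )
    X = sm.add_constant(sub[["p_k_kcal_s", "p_u_kcal_s"]].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("stage-1 design matrix is rank deficient")
    fit = sm.OLS(sub["p_measured_kcal_s"].to_numpy(), X).fit()
    p0, gamma, b0 = fit.params
    return float(gamma), float(b0), float(p0), float(fit.rsquared_adj)


def stage2_fit(
    trials: pd.DataFrame, gamma: float, b0: float, p0: float
) -> float:
    """Closed-form least squares for the downhill quadratic gain b1.

    Uses incline <= 0 records with gamma, b0, p0 held fixed; flat records
    contribute zero weight.
    """
    if p0 <= 0:
        raise InvalidInputError(f"p0 must be > 0, got {p0}")
    sub = trials[trials["incline_deg"] <= 0]
    if (sub["incline_deg"] < 0).sum() < 1:
        raise InvalidInputError("stage 2 needs at least one downhill record")
    p_k = sub["p_k_kcal_s"].to_numpy()
    p_u = sub["p_u_kcal_s"].to_numpy()
    p = sub["p_measured_kcal_s"].to_numpy()
    r = p - gamma * p_k - b0 * p_u - p0
    u = p_u**2 / p0
    denom = float(np.sum(u**2))
    if denom == 0.0:
        raise InvalidInputError("all stage-2 records are flat (sum u^2 = 0)")
    return float(np.sum(r * u) / denom)


def predict_trials(trials: pd.DataFrame, coeffs: CoefficientSet) -> np.ndarray:
    """Piecewise model prediction (kcal/s) for every row of a trials table."""
    p_k = trials["p_k_kcal_s"].to_numpy()
    p_u = trials["p_u_kcal_s"].to_numpy()
    downhill = trials["incline_deg"].to_numpy() < 0
    pred = coeffs.gamma * p_k + coeffs.b0 * p_u + coeffs.p0
    pred = pred + np.where(downhill, coeffs.b1 * p_u**2 / coeffs.p0, 0.0)
    return pred


def fit_by_gender(trials: pd.DataFrame) -> dict[Sex, FitResult]:
    """Run the two-stage calibration separately for women and men.

    Flat (incline = 0) records enter both stages.  The reported RMSD is
    computed from the fitted piecewise model over all of that gender's
    records.  Genders absent from the table are skipped with a warning.
    """
    if len(trials) == 0:
        raise InvalidInputError("empty trials table")
    if "p_k_kcal_s" not in trials.columns:
        trials = compute_regressors(trials)
    results: dict[Sex, FitResult] = {}
    for sex in Sex:
        sub = trials[trials["sex"] == sex.value]
        if len(sub) == 0:
            logger.warning("no %s records; skipping that fit", sex.value)
            continue
        try:
            gamma, b0, p0, adj_r2 = stage1_fit(sub)
            b1 = stage2_fit(sub, gamma, b0, p0)
        except InvalidInputError as exc:
            raise InvalidInputError(f"{sex.value}: {exc}") from exc
        if min(gamma, b0, b1, p0) < 0:
            logger.warning(
                "%s fit produced a negative coefficient: gamma=%.4g b0=%.4g "
                "b1=%.4g p0=%.4g",
                sex.value,
                gamma,
                b0,
                b1,
                p0,
            )
        coeffs = CoefficientSet(gamma=gamma, b0=b0, b1=b1, p0=p0, sex=sex)
        residual_rmsd = rmsd(
            predict_trials(sub, coeffs), sub["p_measured_kcal_s"].to_numpy()
        )
        results[sex] = FitResult(
            coeffs=coeffs,
            adj_r2_stage1=adj_r2,
            rmsd_kcal_s=residual_rmsd,
            n_stage1=int((sub["incline_deg"] >= 0).sum()),
            n_stage2=int((sub["incline_deg"] <= 0).sum()),
        )
    return results


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmsd(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square deviation between paired sequences."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise InvalidInputError("predicted and observed must be equal-length, nonempty")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def percent_error(predicted: float, reference: float) -> float:
    """Absolute percent error 100 |predicted - reference| / reference.

    ``reference`` is the criterion measurement (assumed positive); a zero
    reference is rejected.
    """
    if reference == 0:
        raise InvalidInputError("reference must be nonzero")
    return 100.0 * abs(predicted - reference) / reference


def cadence_regression(
    records: pd.DataFrame,
) -> tuple[float, float]:
    """OLS of the product f*h (m/s) on walking speed v.

    ``records`` needs columns speed_mps, step_freq_hz, height_m.  Returns
    (slope, intercept); the slope is dimensionless, the intercept in m/s.
    """
    for col in ("speed_mps", "step_freq_hz", "height_m"):
        if col not in records.columns:
            raise InvalidInputError(f"missing column {col}")
    v = records["speed_mps"].to_numpy(dtype=float)
    if np.unique(v).size < 2:
        raise SingularDesignError("need at least 2 distinct speeds")
    fh = (records["step_freq_hz"] * records["height_m"]).to_numpy(dtype=float)
    fit = sm.OLS(fh, sm.add_constant(v)).fit()
    intercept, slope = fit.params
    return float(slope), float(intercept)


def adjusted_r2(
    observed: Sequence[float], fitted: Sequence[float], n_params: int
) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = observed.size
    if fitted.size != n:
        raise InvalidInputError("length mismatch")
    if n <= n_params + 1:
        raise InvalidInputError(f"need n > n_params + 1, got n={n}, p={n_params}")
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInputError("observed values are constant")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


# ---------------------------------------------------------------------------
# Trials CSV I/O
# ---------------------------------------------------------------------------

def read_trials_csv(path: "str | Path") -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return compute_regressors(frame)


def write_trials_csv(path: "str | Path", trials: pd.DataFrame) -> None:
    trials[TRIALS_COLUMNS].to_csv(path, index=False)
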