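"""Indirect-calorimetry processing: cumulative kcal series to net walking power.

A portable gas analyzer reports cumulative calorie consumption over a
session.  The gross rate is the ordinary-least-squares slope of cumulative
kcal against time after discarding the first 50 s (start-up transient; the
consumption takes roughly 30 s to stabilize to a linear rate) and the last
10 s.  Subtracting the basal metabolic rate yields the net walking power P
in kcal/s — the quantity the gradient-walking model predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import InvalidInputError, Sex, Subject

__all__ = [
    "CalorimetrySeries",
    "BasalFormula",
    "BasalModel",
    "gross_rate",
    "basal_rate",
    "net_walking_rate",
    "read_calorimetry_csv",
    "write_calorimetry_csv",
]

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class CalorimetrySeries:
    """Cumulative calorie consumption sampled at strictly increasing times."""

    times_s: np.ndarray
    cumulative_kcal: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        kcal = np.asarray(self.cumulative_kcal, dtype=float)
        if times.ndim != 1 or times.shape != kcal.shape:
            raise InvalidInputError("times and cumulative_kcal must be equal-length 1-D")
        if times.size and np.any(np.diff(times) <= 0):
            raise InvalidInputError("times_s must be strictly increasing")
        if kcal.size and np.any(np.diff(kcal) < 0):
            raise InvalidInputError("cumulative_kcal must be nondecreasing")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "cumulative_kcal", kcal)


class BasalFormula(str, Enum):
    HARRIS_BENEDICT_REVISED = "harris_benedict_revised"
    CONSTANT = "constant"


@dataclass(frozen=True)
class BasalModel:
    """Choice of basal metabolic rate model.

    The default is the revised Harris–Benedict equation (Roza & Shizgal,
    1984), which gives the resting expenditure in kcal/day from sex, mass,
    height and age; a fixed per-second constant can be supplied instead.
    """

    formula_id: BasalFormula = BasalFormula.HARRIS_BENEDICT_REVISED
    constant_kcal_per_s: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula_id", BasalFormula(self.formula_id))
        if (
            self.formula_id is BasalFormula.CONSTANT
            and self.constant_kcal_per_s is None
        ):
            raise InvalidInputError("constant basal model requires constant_kcal_per_s")


def gross_rate(
    series: CalorimetrySeries,
    trim_head_s: float = 50.0,
    trim_tail_s: float = 10.0,
) -> float:
    """OLS slope of cumulative kcal on time over the trimmed window, kcal/s."""
    t, y = series.times_s, series.cumulative_kcal
    if t.size == 0:
        raise InvalidInputError("empty series")
    lo = t[0] + trim_head_s
    hi = t[-1] - trim_tail_s
    mask = (t >= lo) & (t <= hi)
    if np.count_nonzero(mask) < 2:
        raise InvalidInputError(
            f"trimmed window [{lo:.1f}, {hi:.1f}] s contains fewer than 2 samples"
        )
    slope, _intercept = np.polyfit(t[mask], y[mask], 1)
    return float(slope)


def basal_rate(subject: Subject, model: BasalModel = BasalModel()) -> float:
    """Basal metabolic rate in kcal/s."""
    if model.formula_id is BasalFormula.CONSTANT:
        return float(model.constant_kcal_per_s)
    # Revised Harris-Benedict (Roza & Shizgal 1984), kcal/day.
    m, h_cm, a = subject.mass_kg, subject.height_m * 100.0, subject.age_yr
    if subject.sex is Sex.FEMALE:
        daily = 447.593 + 9.247 * m + 3.098 * h_cm - 4.330 * a
    else:
        daily = 88.362 + 13.397 * m + 4.799 * h_cm - 5.677 * a
    return daily / SECONDS_PER_DAY


def net_walking_rate(
    series: CalorimetrySeries,
    subject: Subject,
    model: BasalModel = BasalModel(),
    trim_head_s: float = 50.0,
    trim_tail_s: float = 10.0,
    clamp_negative: bool = False,
) -> float:
    """Net walking power P = gross rate − basal rate, kcal/s.

    Negative results (basal exceeding the measured gross rate) are reported
    with a warning unless ``clamp_negative`` is set.
    """
    net = gross_rate(series, trim_head_s, trim_tail_s) - basal_rate(subject, model)
    if net < 0:
        logger.warning("net walking rate is negative (%.4f kcal/s)", net)
        if clamp_negative:
            return 0.0
    return net


# ---------------------------------------------------------------------------
# CSV I/O (irregular sampling tolerated)
# ---------------------------------------------------------------------------

def write_calorimetry_csv(path: "str | Path", series: CalorimetrySeries) -> None:
    pd.DataFrame(
        {"time_s": series.times_s, "cumulative_kcal": series.cumulative_kcal}
    ).to_csv(path, index=False)


def read_calorimetry_csv(path: "str | Path") -> CalorimetrySeries:
    frame = pd.read_csv(path)
    for col in ("time_s", "cumulative_kcal"):
        if col not in frame.columns:
            raise InvalidInputError(f"{path}: missing column {col}")
    return CalorimetrySeries(
        times_s=frame["time_s"].to_numpy(dtype=float),
        cumulative_kcal=frame["cumulative_kcal"].to_numpy(dtype=float),
    )
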