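"""Synthetic cohorts, gait traces, and calorimetry with known ground truth.

Every generator here emulates one of the data streams the pipeline
consumes, built so that the generated study satisfies the gradient-walking
model's assumptions exactly:

* subjects drawn from per-sex truncated-normal anthropometrics whose pooled
  moments approximate the study cohort (mean height 168.3 cm, mass 68.1 kg,
  ages 20-60);
* stride frequency tied to speed and height through the empirical cadence
  line ``f h = 0.52 v + 1.02`` (m/s) plus Gaussian scatter;
* net power equal to the piecewise model prediction plus observation noise
  (default sd 0.016 kcal/s, the residual scale of the calibrated model);
* 10 Hz insole traces with a heel-to-toe rolling stance, a half-cycle
  phase shift between feet, and an optional stuck sensor;
* cumulative-calorie series with a 30 s ramp-in transient and integrated
  measurement noise.

Because the data obey the model by construction, failure of an end-to-end
round trip (simulate -> detect -> rate -> fit) localizes bugs to the
processing code rather than the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .calorimetry import CalorimetrySeries, basal_rate
from .model import (
    CoefficientSet,
    InvalidInputError,
    PUBLISHED_COEFFICIENTS,
    Sex,
    Subject,
    WalkCondition,
    predict_net_power,
)
from .steps import N_SENSORS_PER_FOOT, PressureTrace, SAMPLE_DT_S
from . import calorimetry as _calorimetry
from . import steps as _steps
from .fitting import TRIALS_COLUMNS, compute_regressors

__all__ = [
    "CADENCE_SLOPE",
    "CADENCE_INTERCEPT_MPS",
    "StudyDesign",
    "GaitProfile",
    "Study",
    "sample_subjects",
    "cadence_from_speed",
    "simulate_trial",
    "simulate_trials",
    "simulate_pressure_trace",
    "simulate_calorimetry",
    "make_study",
]

#: Empirical cadence line: f * h = CADENCE_SLOPE * v + CADENCE_INTERCEPT_MPS.
CADENCE_SLOPE = 0.52
CADENCE_INTERCEPT_MPS = 1.02

_MIN_CADENCE_HZ = 0.1


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial treadmill study layout and noise levels.

    The incline set matches the calibration protocol (0, +-4, +-9, +-14
    degrees); the speed set brackets normal walking.  ``noise_sd_kcal_s``
    is the sd of the observation noise added to the model's net power;
    ``cadence_noise_sd_mps`` is the sd of the scatter of f*h about the
    cadence line, in m/s.
    """

    n_subjects: int = 40
    incline_set_deg: tuple = (-14.0, -9.0, -4.0, 0.0, 4.0, 9.0, 14.0)
    speed_set_mps: tuple = (0.8, 1.1, 1.4, 1.7, 2.0)
    session_duration_s: float = 300.0
    noise_sd_kcal_s: float = 0.016
    cadence_noise_sd_mps: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        if self.session_duration_s <= 60:
            raise InvalidInputError("session_duration_s must exceed 60 s")
        if self.noise_sd_kcal_s < 0 or self.cadence_noise_sd_mps < 0:
            raise InvalidInputError("noise levels must be >= 0")


@dataclass(frozen=True)
class GaitProfile:
    """Shape of the simulated gait cycle for one session.

    ``sensor_onsets`` are heel-to-toe loading onsets as fractions of the
    stance phase; each sensor stays loaded for half the stance.
    ``faulty_sensor`` is a (channel, stuck_value) pair, channel 0-7 on the
    left foot and 8-15 on the right.
    """

    stride_freq_hz: float
    stance_fraction: float = 0.62
    sensor_onsets: tuple = tuple(0.5 * i / (N_SENSORS_PER_FOOT - 1) for i in range(N_SENSORS_PER_FOOT))
    faulty_sensor: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.stride_freq_hz <= 0:
            raise InvalidInputError("stride_freq_hz must be > 0")
        if not (0.0 < self.stance_fraction < 1.0):
            raise InvalidInputError("stance_fraction must lie strictly in (0, 1)")
        if len(self.sensor_onsets) != N_SENSORS_PER_FOOT:
            raise InvalidInputError(f"need {N_SENSORS_PER_FOOT} sensor onsets")
        if self.faulty_sensor is not None:
            idx, value = self.faulty_sensor
            if not (0 <= idx < 2 * N_SENSORS_PER_FOOT) or value not in (0, 1, 2):
                raise InvalidInputError("faulty_sensor must be (0-15, value in {0,1,2})")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_subjects(n: int, seed) -> list[Subject]:
    """Draw ``n`` subjects with 50/50 sex ratio (deterministic under seed).

    Per-sex anthropometrics (women: height ~N(161, 6) cm, mass ~N(61, 10)
    kg; men: height ~N(175, 6) cm, mass ~N(74, 10) kg; truncated at +-3 sd)
    are synthetic choices whose pooled moments approximate the cohort's
    published means, not estimates of the real per-sex distributions.
    Ages are truncated-normal(43.6, 15) on [20, 60] years.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = _rng(seed)
    sexes = rng.permuted(
        np.array([Sex.FEMALE, Sex.MALE] * (n // 2 + 1), dtype=object)[:n]
    )
    subjects = []
    for sex in sexes:
        if sex is Sex.FEMALE:
            h_cm = _truncated_normal(rng, 161.0, 6.0, 143.0, 179.0, 1)[0]
            m_kg = _truncated_normal(rng, 61.0, 10.0, 40.0, 91.0, 1)[0]
        else:
            h_cm = _truncated_normal(rng, 175.0, 6.0, 157.0, 193.0, 1)[0]
            m_kg = _truncated_normal(rng, 74.0, 10.0, 44.0, 104.0, 1)[0]
        age = _truncated_normal(rng, 43.6, 15.0, 20.0, 60.0, 1)[0]
        subjects.append(
            Subject(sex=sex, mass_kg=float(m_kg), height_m=float(h_cm) / 100.0, age_yr=float(age))
        )
    return subjects


# ---------------------------------------------------------------------------
# Cadence and trials
# ---------------------------------------------------------------------------

def cadence_from_speed(
    speed_mps: float,
    height_m: float,
    noise_sd_mps: float = 0.0,
    seed=None,
) -> float:
    """Stride frequency implied by the cadence line, in Hz.

    ``f = (0.52 v + 1.02 + eps) / h`` with ``eps ~ N(0, noise_sd_mps)`` on
    the f*h product; floored at 0.1 Hz.
    """
    if speed_mps <= 0 or height_m <= 0:
        raise InvalidInputError("speed and height must be positive")
    fh = CADENCE_SLOPE * speed_mps + CADENCE_INTERCEPT_MPS
    if noise_sd_mps > 0:
        fh += _rng(seed).normal(0.0, noise_sd_mps)
    return max(fh / height_m, _MIN_CADENCE_HZ)


def simulate_trial(
    subject: Subject,
    speed_mps: float,
    incline_deg: float,
    coeffs: CoefficientSet,
    noise_sd_kcal_s: float = 0.016,
    cadence_noise_sd_mps: float = 0.1,
    seed=None,
) -> dict:
    """One participant x condition observation as a trials-table row (dict).

    Stride frequency is drawn from the cadence line (zero when standing
    still); the measured net power is the piecewise model prediction plus
    N(0, noise_sd_kcal_s).
    """
    rng = _rng(seed)
    if speed_mps == 0:
        f = 0.0
    else:
        f = cadence_from_speed(speed_mps, subject.height_m, cadence_noise_sd_mps, rng)
    cond = WalkCondition(speed_mps=speed_mps, incline_deg=incline_deg, step_freq_hz=f)
    p = predict_net_power(coeffs, subject, cond)
    if noise_sd_kcal_s > 0:
        p += rng.normal(0.0, noise_sd_kcal_s)
    return {
        "sex": subject.sex.value,
        "mass_kg": subject.mass_kg,
        "height_m": subject.height_m,
        "speed_mps": speed_mps,
        "incline_deg": incline_deg,
        "step_freq_hz": f,
        "p_measured_kcal_s": p,
    }


def simulate_trials(
    n_per_gender: int,
    design: StudyDesign = StudyDesign(),
    coeffs_by_sex: "dict[Sex, CoefficientSet] | None" = None,
    seed=None,
) -> pd.DataFrame:
    """Trials table with ``n_per_gender`` rows per sex, regressors included.

    Subjects cycle through the factorial incline x speed grid of ``design``
    until the requested count is reached; powers come from
    :func:`simulate_trial` with the design's noise levels.  Used for
    parameter-recovery studies that need the trials table directly, without
    materializing traces and calorimetry.
    """
    if n_per_gender < 1:
        raise InvalidInputError("n_per_gender must be >= 1")
    if coeffs_by_sex is None:
        coeffs_by_sex = PUBLISHED_COEFFICIENTS
    coeffs_by_sex = {Sex(k): v for k, v in coeffs_by_sex.items()}
    rng = _rng(seed if seed is not None else design.seed)
    rows = []
    for sex in (Sex.FEMALE, Sex.MALE):
        count = 0
        si = 0
        while count < n_per_gender:
            for subject in sample_subjects(16, rng):
                if subject.sex is not sex:
                    continue
                for incline in design.incline_set_deg:
                    for speed in design.speed_set_mps:
                        if count >= n_per_gender:
                            break
                        row = simulate_trial(
                            subject,
                            speed,
                            incline,
                            coeffs_by_sex[sex],
                            design.noise_sd_kcal_s,
                            design.cadence_noise_sd_mps,
                            rng,
                        )
                        rows.append({"subject_id": f"{sex.value[0]}{si:04d}", **row})
                        count += 1
                si += 1
    return compute_regressors(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Insole traces
# ---------------------------------------------------------------------------

def simulate_pressure_trace(
    profile: GaitProfile, duration_s: float, seed=None
) -> tuple[PressureTrace, tuple[int, int]]:
    """Generate a 10 Hz insole trace and its true per-foot toe-off counts.

    Each foot cycles at ``stride_freq_hz`` with the right foot half a cycle
    out of phase.  During stance the eight sensors load heel to toe (value
    2 when loaded, with 10% of loaded readings flickering to 1); during
    swing all sensors read 0.  A faulty sensor reads its stuck value at
    every frame.  Mid-stance sums comfortably exceed the upper detection
    threshold while swing sums stay below the lower one.
    """
    if duration_s < 10:
        raise InvalidInputError("duration_s must be >= 10 s")
    rng = _rng(seed)
    n = int(round(duration_s / SAMPLE_DT_S))
    t = SAMPLE_DT_S * np.arange(n)
    period = 1.0 / profile.stride_freq_hz
    onsets = np.asarray(profile.sensor_onsets)

    feet = []
    counts = []
    for phase_offset in (0.0, 0.5):
        phase = np.mod(t / period - phase_offset, 1.0)
        in_stance = phase < profile.stance_fraction
        s = np.where(in_stance, phase / profile.stance_fraction, np.nan)
        # sensor j loaded while the stance sub-phase is inside its window
        loaded = (
            (s[:, None] >= onsets[None, :])
            & (s[:, None] < onsets[None, :] + 0.5)
            & in_stance[:, None]
        )
        values = np.where(loaded, 2, 0).astype(np.int64)
        flicker = rng.random(values.shape) < 0.1
        values[loaded & flicker] = 1
        feet.append(values)
        on = in_stance
        counts.append(int(np.count_nonzero(on[:-1] & ~on[1:])))

    left, right = feet
    if profile.faulty_sensor is not None:
        idx, value = profile.faulty_sensor
        if idx < N_SENSORS_PER_FOOT:
            left[:, idx] = value
        else:
            right[:, idx - N_SENSORS_PER_FOOT] = value
    trace = PressureTrace(left=left, right=right)
    return trace, (counts[0], counts[1])


# ---------------------------------------------------------------------------
# Calorimetry
# ---------------------------------------------------------------------------

def simulate_calorimetry(
    net_rate_kcal_s: float,
    basal_rate_kcal_s: float,
    duration_s: float,
    noise_sd_kcal: float = 0.005,
    seed=None,
    sample_dt_s: float = 1.0,
    ramp_s: float = 30.0,
) -> CalorimetrySeries:
    """Cumulative-calorie series with a ramp-in transient and integrated noise.

    The instantaneous rate rises linearly from the basal rate to
    basal + net over the first ``ramp_s`` seconds (stabilization of the gas
    measurement), then stays constant.  Per-sample increments get
    N(0, noise_sd_kcal) noise and are clipped at zero so the cumulative
    series is nondecreasing.
    """
    if duration_s < 0:
        raise InvalidInputError("duration_s must be >= 0")
    if basal_rate_kcal_s < 0 or net_rate_kcal_s + basal_rate_kcal_s < 0:
        raise InvalidInputError("gross rate (net + basal) must be >= 0")
    rng = _rng(seed)
    times = np.arange(0.0, duration_s + sample_dt_s / 2, sample_dt_s)
    ramp = np.minimum(times / ramp_s, 1.0) if ramp_s > 0 else np.ones_like(times)
    rate = basal_rate_kcal_s + net_rate_kcal_s * ramp
    increments = rate[1:] * sample_dt_s
    if noise_sd_kcal > 0:
        increments = np.clip(increments + rng.normal(0.0, noise_sd_kcal, increments.size), 0.0, None)
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    return CalorimetrySeries(times_s=times, cumulative_kcal=cumulative)


# ---------------------------------------------------------------------------
# Whole-study factory
# ---------------------------------------------------------------------------

@dataclass
class Study:
    """A materialized synthetic study.

    ``manifest`` and ``ground_truth`` are always present; ``traces`` and
    ``calorimetry`` hold in-memory objects keyed by session id when no
    output directory was given (otherwise the data live in the CSV files
    named by the manifest).
    """

    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    subjects: dict
    traces: Optional[dict] = None
    calorimetry: Optional[dict] = None

    def true_trials(self) -> pd.DataFrame:
        """Trials table built from the ground truth (no detection errors)."""
        merged = self.manifest.merge(self.ground_truth, on="session_id")
        out = merged.rename(
            columns={
                "true_step_freq_hz": "step_freq_hz",
                "true_net_rate_kcal_s": "p_measured_kcal_s",
            }
        )
        return out[TRIALS_COLUMNS]


MANIFEST_COLUMNS = [
    "session_id",
    "subject_id",
    "sex",
    "mass_kg",
    "height_m",
    "age_yr",
    "speed_mps",
    "incline_deg",
    "pressure_path",
    "calorimetry_path",
]

GROUND_TRUTH_COLUMNS = [
    "session_id",
    "true_step_freq_hz",
    "true_net_rate_kcal_s",
    "gamma",
    "b0",
    "b1",
    "p0_kcal_per_s",
]


def make_study(
    design: StudyDesign,
    coeffs_by_sex: "dict[Sex, CoefficientSet] | None" = None,
    out_dir: "str | Path | None" = None,
) -> Study:
    """Materialize every subject x incline x speed session of a study.

    For each session the generator draws the stride frequency, builds the
    matching insole trace, computes the noisy net power from the piecewise
    model, and synthesizes the calorimetry series at gross rate
    net + basal (basal from the revised Harris-Benedict equation, the same
    model the processing side subtracts).  With ``out_dir`` set, pressure
    and calorimetry CSVs plus ``manifest.csv`` and ``ground_truth.csv`` are
    written there; otherwise everything stays in memory.

    Fully deterministic under ``design.seed``.
    """
    if coeffs_by_sex is None:
        coeffs_by_sex = PUBLISHED_COEFFICIENTS
    coeffs_by_sex = {Sex(k): v for k, v in coeffs_by_sex.items()}
    rng = _rng(design.seed)
    subjects = sample_subjects(design.n_subjects, rng)
    base = Path(out_dir) if out_dir is not None else None
    if base is not None:
        base.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    truth_rows = []
    traces: Optional[dict] = None if base is not None else {}
    calseries: Optional[dict] = None if base is not None else {}
    subj_map = {}

    for si, subject in enumerate(subjects):
        subject_id = f"S{si:03d}"
        subj_map[subject_id] = subject
        coeffs = coeffs_by_sex[subject.sex]
        b_rate = basal_rate(subject)
        for incline in design.incline_set_deg:
            for speed in design.speed_set_mps:
                session_id = f"{subject_id}_i{incline:+.0f}_v{speed:.1f}"
                f = cadence_from_speed(
                    speed, subject.height_m, design.cadence_noise_sd_mps, rng
                )
                cond = WalkCondition(speed, incline, f)
                p_net = predict_net_power(coeffs, subject, cond)
                if design.noise_sd_kcal_s > 0:
                    p_net += rng.normal(0.0, design.noise_sd_kcal_s)
                p_net = max(p_net, -b_rate)  # gross rate cannot go negative
                trace, _true_counts = simulate_pressure_trace(
                    GaitProfile(stride_freq_hz=f), design.session_duration_s, rng
                )
                series = simulate_calorimetry(
                    p_net, b_rate, design.session_duration_s, seed=rng
                )
                if base is not None:
                    p_path = f"pressure_{session_id}.csv"
                    c_path = f"calorimetry_{session_id}.csv"
                    _steps.write_pressure_csv(base / p_path, trace)
                    _calorimetry.write_calorimetry_csv(base / c_path, series)
                else:
                    p_path = c_path = ""
                    traces[session_id] = trace
                    calseries[session_id] = series
                manifest_rows.append(
                    (
                        session_id,
                        subject_id,
                        subject.sex.value,
                        subject.mass_kg,
                        subject.height_m,
                        subject.age_yr,
                        speed,
                        incline,
                        p_path,
                        c_path,
                    )
                )
                truth_rows.append(
                    (
                        session_id,
                        f,
                        p_net,
                        coeffs.gamma,
                        coeffs.b0,
                        coeffs.b1,
                        coeffs.p0,
                    )
                )

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    ground_truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    if base is not None:
        manifest.to_csv(base / "manifest.csv", index=False)
        ground_truth.to_csv(base / "ground_truth.csv", index=False)
    return Study(
        manifest=manifest,
        ground_truth=ground_truth,
        subjects=subj_map,
        traces=traces,
        calorimetry=calseries,
    )
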