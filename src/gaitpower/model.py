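"""Piecewise mechanistic model of walking energy expenditure on a gradient.

The model treats the net (above-basal) metabolic power ``P`` of a walker of
body mass ``M`` moving at speed ``v`` on a surface inclined by ``theta`` as a
piecewise function of two mechanical power regressors:

* a kinetic term ``P_K = 2 M v^2 f`` — the rate of work done accelerating and
  decelerating the legs, with ``f`` the stride frequency of one foot;
* a potential term ``P_U = M g v sin(theta)`` — the rate of change of
  gravitational potential energy, positive uphill and negative downhill.

On flat and uphill ground (``theta >= 0``)::

    P = gamma * P_K + b0 * P_U + P0

while downhill (``theta < 0``) an extra quadratic term captures the braking
cost that makes steep descents expensive again::

    P = gamma * P_K + b0 * P_U + b1 * P_U**2 / P0 + P0

``gamma``, ``b0`` and ``b1`` are dimensionless fitted coefficients and ``P0``
(kcal/s) is the constant offset; ``b1`` is expressed in units of ``P0`` so it
stays dimensionless.  The two branches agree at ``theta = 0`` because
``P_U(0) = 0``.

Internally all mechanical powers are computed in watts and converted to
kcal/s at the model boundary (1 kcal = 4184 J); angles are accepted in
degrees at every public interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

__all__ = [
    "GRAVITY_M_S2",
    "KCAL_JOULES",
    "ALPHA_FEMALE",
    "ALPHA_MALE",
    "VALIDATED_INCLINE_DEG",
    "Sex",
    "Subject",
    "WalkCondition",
    "CoefficientSet",
    "PhysicalConstants",
    "PUBLISHED_COEFFICIENTS",
    "InvalidInputError",
    "kinetic_power",
    "potential_power",
    "predict_net_power",
    "predicted_minutes_rate",
    "beta_from_coefficients",
    "leg_mass_fraction",
    "read_coefficients",
    "write_coefficients",
]

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: Standard gravitational acceleration, m/s^2.
GRAVITY_M_S2 = 9.80665

#: Thermochemical calorie: joules per kilocalorie.
KCAL_JOULES = 4184.0

#: Leg-to-body mass ratio (both legs / body), by sex, from anatomical tables.
ALPHA_FEMALE = 0.185
ALPHA_MALE = 0.165

#: Incline range (degrees, absolute) over which the model was calibrated.
VALIDATED_INCLINE_DEG = 14.0


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants, overridable for sensitivity analyses."""

    g: float = GRAVITY_M_S2
    kcal_joules: float = KCAL_JOULES
    alpha_female: float = ALPHA_FEMALE
    alpha_male: float = ALPHA_MALE

    def alpha(self, sex: "Sex | str") -> float:
        return self.alpha_female if Sex(sex) is Sex.FEMALE else self.alpha_male


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class Subject:
    """A study participant.

    Parameters
    ----------
    sex
        ``Sex.FEMALE`` or ``Sex.MALE`` (strings accepted).
    mass_kg
        Body mass ``M`` in kg, > 0.
    height_m
        Standing height ``h`` in m; also the proxy for step length in the
        cadence relation ``v ~ f h``.
    age_yr
        Age in years, >= 0 (used by the basal-rate formula).
    """

    sex: Sex
    mass_kg: float
    height_m: float
    age_yr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if not (self.mass_kg > 0 and math.isfinite(self.mass_kg)):
            raise InvalidInputError(f"mass_kg must be positive, got {self.mass_kg}")
        if not (0.5 < self.height_m < 2.5):
            raise InvalidInputError(
                f"height_m must lie in (0.5, 2.5) m, got {self.height_m}"
            )
        if self.age_yr < 0:
            raise InvalidInputError(f"age_yr must be >= 0, got {self.age_yr}")


@dataclass(frozen=True)
class WalkCondition:
    """One treadmill condition: speed, incline, and measured stride frequency.

    ``step_freq_hz`` is strides per second of one foot (toe-off to toe-off),
    averaged over both feet.  Positive inclines are uphill.
    """

    speed_mps: float
    incline_deg: float
    step_freq_hz: float

    def __post_init__(self) -> None:
        if self.speed_mps < 0:
            raise InvalidInputError(f"speed_mps must be >= 0, got {self.speed_mps}")
        if self.step_freq_hz < 0:
            raise InvalidInputError(
                f"step_freq_hz must be >= 0, got {self.step_freq_hz}"
            )
        if abs(self.incline_deg) > 90:
            raise InvalidInputError(
                f"incline_deg must satisfy |theta| <= 90, got {self.incline_deg}"
            )
        if abs(self.incline_deg) > VALIDATED_INCLINE_DEG:
            warnings.warn(
                f"incline {self.incline_deg} deg is outside the validated "
                f"range |theta| <= {VALIDATED_INCLINE_DEG} deg",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CoefficientSet:
    """Fitted model coefficients gamma, b0, b1 (dimensionless) and P0 (kcal/s)."""

    gamma: float
    b0: float
    b1: float
    p0: float
    sex: Union[Sex, None] = None

    def __post_init__(self) -> None:
        for name in ("gamma", "b0", "b1", "p0"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidInputError(f"{name} must be finite, got {value}")
        if self.p0 <= 0:
            raise InvalidInputError(f"p0 must be > 0, got {self.p0}")
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex(self.sex))


#: Gender-pooled coefficient sets published for this model (P0 in kcal/s).
PUBLISHED_COEFFICIENTS: dict[Sex, CoefficientSet] = {
    Sex.FEMALE: CoefficientSet(gamma=0.662, b0=1.591, b1=0.575, p0=0.042, sex=Sex.FEMALE),
    Sex.MALE: CoefficientSet(gamma=0.517, b0=1.694, b1=1.086, p0=0.058, sex=Sex.MALE),
}


def leg_mass_fraction(sex: "Sex | str", constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Ratio alpha of combined leg mass to body mass for the given sex."""
    return constants.alpha(sex)


# ---------------------------------------------------------------------------
# Mechanical power regressors
# ---------------------------------------------------------------------------

def kinetic_power(
    mass_kg: float,
    speed_mps: float,
    step_freq_hz: float,
) -> float:
    """Kinetic power regressor ``P_K = 2 M v^2 f`` in watts.

    Each stride accelerates and decelerates both legs once; the work per
    cycle is ``4 * (1/2) m v0^2 = 2 alpha beta^2 M v^2`` with the
    unmeasurable ratios alpha and beta absorbed into the fitted gamma, which
    leaves ``2 M v^2`` per cycle times the stride frequency.
    """
    if mass_kg < 0 or speed_mps < 0 or step_freq_hz < 0:
        raise InvalidInputError(
            "kinetic_power arguments must be nonnegative, got "
            f"M={mass_kg}, v={speed_mps}, f={step_freq_hz}"
        )
    return 2.0 * mass_kg * speed_mps**2 * step_freq_hz


def potential_power(
    mass_kg: float,
    speed_mps: float,
    incline_deg: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Potential power ``P_U = M g v sin(theta)`` in watts (signed)."""
    if mass_kg <= 0:
        raise InvalidInputError(f"mass_kg must be > 0, got {mass_kg}")
    if speed_mps < 0:
        raise InvalidInputError(f"speed_mps must be >= 0, got {speed_mps}")
    return mass_kg * constants.g * speed_mps * math.sin(math.radians(incline_deg))


# ---------------------------------------------------------------------------
# The piecewise model
# ---------------------------------------------------------------------------

def predict_net_power(
    coeffs: CoefficientSet,
    subject: Subject,
    cond: WalkCondition,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Net (above-basal) energy expenditure rate in kcal/s.

    Evaluates the uphill branch for ``theta >= 0`` and the downhill branch
    (with the quadratic ``b1 * P_U^2 / P0`` term) for ``theta < 0``.  The
    branches coincide at ``theta = 0`` since ``P_U`` vanishes there.
    """
    if coeffs.p0 <= 0:
        raise InvalidInputError(
            f"p0 must be > 0 for the downhill branch, got {coeffs.p0}"
        )
    p_k = kinetic_power(subject.mass_kg, cond.speed_mps, cond.step_freq_hz)
    p_u = potential_power(
        subject.mass_kg, cond.speed_mps, cond.incline_deg, constants
    )
    p_k /= constants.kcal_joules
    p_u /= constants.kcal_joules
    power = coeffs.gamma * p_k + coeffs.b0 * p_u + coeffs.p0
    if cond.incline_deg < 0:
        power += coeffs.b1 * p_u**2 / coeffs.p0
    return power


def predicted_minutes_rate(
    coeffs: CoefficientSet,
    subject: Subject,
    cond: WalkCondition,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """As :func:`predict_net_power` but in kcal/min."""
    return 60.0 * predict_net_power(coeffs, subject, cond, constants)


def beta_from_coefficients(gamma: float, alpha: float, b0: float) -> float:
    """Peak-leg-speed to walking-speed ratio ``beta = sqrt(gamma / (alpha b0))``.

    The fitted kinetic gain decomposes as ``gamma = alpha beta^2 / eta_K``
    where ``eta_K`` is the chemical-to-kinetic conversion efficiency.
    Assuming ``eta_K`` equals the potential efficiency ``eta_U = 1 / b0``
    lets beta be recovered from the fitted coefficients alone.
    """
    if gamma <= 0 or alpha <= 0 or b0 <= 0:
        raise InvalidInputError(
            f"gamma, alpha, b0 must all be > 0, got {gamma}, {alpha}, {b0}"
        )
    return math.sqrt(gamma / (alpha * b0))


# ---------------------------------------------------------------------------
# Coefficient file I/O
# ---------------------------------------------------------------------------

_COEFF_KEYS = ("gamma", "b0", "b1", "p0_kcal_per_s", "sex")


def write_coefficients(path: "str | Path", coeffs: CoefficientSet) -> None:
    """Write a coefficient set as a flat ``key = value`` text file."""
    sex = coeffs.sex.value if coeffs.sex is not None else ""
    lines = [
        f"gamma = {coeffs.gamma!r}",
        f"b0 = {coeffs.b0!r}",
        f"b1 = {coeffs.b1!r}",
        f"p0_kcal_per_s = {coeffs.p0!r}",
        f"sex = {sex}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients(path: "str | Path") -> CoefficientSet:
    """Read a coefficient set written by :func:`write_coefficients`.

    Rejects files with missing or unparseable keys.
    """
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InvalidInputError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    missing = [k for k in _COEFF_KEYS if k not in entries]
    if missing:
        raise InvalidInputError(f"{path}: missing keys {missing}")
    try:
        numeric = {k: float(entries[k]) for k in _COEFF_KEYS[:4]}
    except ValueError as exc:
        raise InvalidInputError(f"{path}: non-numeric coefficient: {exc}") from exc
    sex = Sex(entries["sex"]) if entries["sex"] else None
    return CoefficientSet(
        gamma=numeric["gamma"],
        b0=numeric["b0"],
        b1=numeric["b1"],
        p0=numeric["p0_kcal_per_s"],
        sex=sex,
    )
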