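"""Foot-contact detection and stride frequency from insole pressure traces.

An insole records eight pressure sensors per foot at 10 Hz, each quantized
to {0, 1, 2}.  Foot contact is classified from the per-foot pressure sum
with a two-threshold hysteresis state machine: starting on-ground, a frame
goes off-ground only when the sum drops strictly below the lower threshold
(default 2) and returns on-ground only when it rises strictly above the
upper threshold (default 5).  The dual threshold makes the detector robust
to a sensor stuck at a nonzero value or to residual pressure during swing,
which would defeat a simple sum-is-zero rule.

Stride frequency per foot is the count of on-ground to off-ground
transitions divided by the observation time, after trimming the first 50 s
and last 10 s of the session; the reported frequency is the mean of both
feet.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import InvalidInputError

__all__ = [
    "N_SENSORS_PER_FOOT",
    "SAMPLE_DT_S",
    "Side",
    "ContactStatus",
    "PressureTrace",
    "ContactSeries",
    "DetectorConfig",
    "TraceTooShortError",
    "foot_pressure_sum",
    "contact_states",
    "step_count",
    "step_events",
    "step_frequency",
    "read_pressure_csv",
    "write_pressure_csv",
]

N_SENSORS_PER_FOOT = 8
SAMPLE_DT_S = 0.1
_MAX_SUM = 2 * N_SENSORS_PER_FOOT  # each of 8 sensors saturates at 2


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class ContactStatus(str, Enum):
    ON_GROUND = "on_ground"
    OFF_GROUND = "off_ground"


class TraceTooShortError(InvalidInputError):
    """Trace shorter than the head + tail trim window."""


@dataclass(frozen=True)
class DetectorConfig:
    """Hysteresis thresholds (on the 0–16 pressure sum) and trim window."""

    lower_threshold: int = 2
    upper_threshold: int = 5
    trim_head_s: float = 50.0
    trim_tail_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower_threshold <= self.upper_threshold <= _MAX_SUM):
            raise InvalidInputError(
                "need 0 <= lower_threshold <= upper_threshold <= "
                f"{_MAX_SUM}, got {self.lower_threshold}, {self.upper_threshold}"
            )
        if self.trim_head_s < 0 or self.trim_tail_s < 0:
            raise InvalidInputError("trims must be >= 0")


@dataclass(frozen=True)
class PressureTrace:
    """A 10 Hz, 16-channel insole recording.

    ``left`` and ``right`` are (n_frames, 8) integer arrays with values in
    {0, 1, 2}, ordered heel to toe.
    """

    left: np.ndarray
    right: np.ndarray
    start_time_s: float = 0.0
    dt_s: float = SAMPLE_DT_S

    def __post_init__(self) -> None:
        left = np.asarray(self.left).astype(np.int8, casting="same_kind", copy=False)
        right = np.asarray(self.right).astype(np.int8, casting="same_kind", copy=False)
        for name, arr in (("left", left), ("right", right)):
            if arr.ndim != 2 or arr.shape[1] != N_SENSORS_PER_FOOT:
                raise InvalidInputError(
                    f"{name} must have shape (n, {N_SENSORS_PER_FOOT})"
                )
            if arr.size and (arr.min() < 0 or arr.max() > 2):
                raise InvalidInputError(f"{name} sensor values must be in {{0,1,2}}")
        if left.shape[0] != right.shape[0]:
            raise InvalidInputError("left and right must have equal frame counts")
        if self.dt_s <= 0:
            raise InvalidInputError(f"dt_s must be > 0, got {self.dt_s}")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def n_frames(self) -> int:
        return self.left.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt_s

    def times(self) -> np.ndarray:
        return self.start_time_s + self.dt_s * np.arange(self.n_frames)


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame contact status for one foot."""

    statuses: tuple
    side: Side = Side.LEFT

    def __post_init__(self) -> None:
        statuses = tuple(ContactStatus(s) for s in self.statuses)
        if statuses and statuses[0] is not ContactStatus.ON_GROUND:
            raise InvalidInputError("first status must be on_ground")
        object.__setattr__(self, "statuses", statuses)
        object.__setattr__(self, "side", Side(self.side))

    def __len__(self) -> int:
        return len(self.statuses)


def foot_pressure_sum(trace: PressureTrace, side: "Side | str") -> np.ndarray:
    """Per-frame sum of the eight sensors of one foot (integers in [0, 16])."""
    if trace.n_frames == 0:
        raise InvalidInputError("empty trace")
    arr = trace.left if Side(side) is Side.LEFT else trace.right
    return arr.sum(axis=1)


def _hysteresis(sums: np.ndarray, lower: int, upper: int) -> np.ndarray:
    """Vectorized hysteresis recursion; returns a boolean on-ground array.

    Equivalent to the sequential rule (first frame on-ground; switch off
    when the sum drops strictly below ``lower``, back on when it rises
    strictly above ``upper``): each frame's state is the one demanded by
    the most recent threshold crossing, so it can be read off with a
    running maximum over crossing indices.
    """
    crossing = np.zeros(sums.size, dtype=np.int8)
    crossing[sums > upper] = 1
    crossing[sums < lower] = -1
    crossing[0] = 1  # first frame pinned on-ground
    idx = np.where(crossing != 0, np.arange(sums.size), 0)
    last = np.maximum.accumulate(idx)
    return crossing[last] > 0


def contact_states(
    sums: Sequence[int],
    config: DetectorConfig = DetectorConfig(),
    side: "Side | str" = Side.LEFT,
) -> ContactSeries:
    """Run the hysteresis state machine over a pressure-sum sequence.

    The first frame is on-ground.  From on-ground, a sum strictly below
    ``lower_threshold`` switches to off-ground; from off-ground, a sum
    strictly above ``upper_threshold`` switches back.  Boundary values leave
    the state unchanged.
    """
    sums = np.asarray(sums)
    if sums.size == 0:
        raise InvalidInputError("empty sum sequence")
    if sums.min() < 0 or sums.max() > _MAX_SUM:
        raise InvalidInputError(f"pressure sums must lie in [0, {_MAX_SUM}]")
    on = _hysteresis(sums, config.lower_threshold, config.upper_threshold)
    statuses = tuple(
        ContactStatus.ON_GROUND if flag else ContactStatus.OFF_GROUND for flag in on
    )
    return ContactSeries(statuses=statuses, side=side)


def step_count(states: ContactSeries) -> int:
    """Number of on-ground to off-ground transitions (toe-offs)."""
    if len(states) == 0:
        raise InvalidInputError("empty contact series")
    on = np.array(
        [s is ContactStatus.ON_GROUND for s in states.statuses], dtype=bool
    )
    return int(np.count_nonzero(on[:-1] & ~on[1:]))


def step_events(
    states: ContactSeries, times: np.ndarray
) -> pd.DataFrame:
    """Tabulate gait events: toe-off at the first off-ground frame of each
    swing, heel-strike at the first on-ground frame of each stance."""
    if len(states) != len(times):
        raise InvalidInputError("states and times length mismatch")
    on = np.array(
        [s is ContactStatus.ON_GROUND for s in states.statuses], dtype=bool
    )
    toe_off = np.flatnonzero(on[:-1] & ~on[1:]) + 1
    heel_strike = np.flatnonzero(~on[:-1] & on[1:]) + 1
    rows = [(float(times[i]), states.side.value, "toe_off") for i in toe_off]
    rows += [(float(times[i]), states.side.value, "heel_strike") for i in heel_strike]
    frame = pd.DataFrame(rows, columns=["time_s", "side", "event"])
    return frame.sort_values("time_s", kind="stable").reset_index(drop=True)


def step_frequency(
    trace: PressureTrace, config: DetectorConfig = DetectorConfig()
) -> float:
    """Mean of the two per-foot stride frequencies, in Hz.

    Trims ``trim_head_s`` from the start and ``trim_tail_s`` from the end of
    the trace, counts toe-off transitions per foot inside the trimmed window
    (a transition counts if its off-ground frame lies inside), and divides
    by the trimmed duration.
    """
    trimmed = trace.duration_s - config.trim_head_s - config.trim_tail_s
    if trimmed <= 0:
        raise TraceTooShortError(
            f"trace of {trace.duration_s:.1f} s is shorter than the "
            f"{config.trim_head_s:.0f}+{config.trim_tail_s:.0f} s trims"
        )
    i0 = int(round(config.trim_head_s / trace.dt_s))
    i1 = trace.n_frames - int(round(config.trim_tail_s / trace.dt_s))
    freqs = []
    for side in Side:
        sums = foot_pressure_sum(trace, side)[i0:i1]
        if sums.min() < 0 or sums.max() > _MAX_SUM:
            raise InvalidInputError(f"pressure sums must lie in [0, {_MAX_SUM}]")
        on = _hysteresis(sums, config.lower_threshold, config.upper_threshold)
        n_steps = int(np.count_nonzero(on[:-1] & ~on[1:]))
        freqs.append(n_steps / (sums.size * trace.dt_s))
    return float(np.mean(freqs))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PRESSURE_COLUMNS = (
    ["time_s"]
    + [f"L{i}" for i in range(1, 9)]
    + [f"R{i}" for i in range(1, 9)]
)


def write_pressure_csv(path: "str | Path", trace: PressureTrace) -> None:
    frame = pd.DataFrame(
        np.column_stack([trace.times(), trace.left, trace.right]),
        columns=_PRESSURE_COLUMNS,
    )
    frame[_PRESSURE_COLUMNS[1:]] = frame[_PRESSURE_COLUMNS[1:]].astype(int)
    frame.to_csv(path, index=False, float_format="%.1f")


def read_pressure_csv(path: "str | Path") -> PressureTrace:
    """Read the ``time_s,L1..L8,R1..R8`` dialect; checks strict 0.1 s spacing."""
    frame = pd.read_csv(path)
    missing = [c for c in _PRESSURE_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    if len(frame) < 2:
        raise InvalidInputError(f"{path}: need at least 2 frames")
    times = frame["time_s"].to_numpy(dtype=float)
    if np.any(np.abs(np.diff(times) - SAMPLE_DT_S) > 1e-6):
        raise InvalidInputError(f"{path}: sampling must be uniform at {SAMPLE_DT_S} s")
    left = frame[[f"L{i}" for i in range(1, 9)]].to_numpy()
    right = frame[[f"R{i}" for i in range(1, 9)]].to_numpy()
    if not (np.all(left == left.astype(np.int64)) and np.all(right == right.astype(np.int64))):
        raise InvalidInputError(f"{path}: sensor values must be integers")
    return PressureTrace(
        left=left.astype(np.int8),
        right=right.astype(np.int8),
        start_time_s=float(times[0]),
    )
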