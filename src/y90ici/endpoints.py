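"""RECIST response categories and time-to-event endpoints.

Response assessment follows the RECIST categories applied to the
sphere-equivalent diameter of each compartment: progressive disease is
at least a 20% diameter increase over baseline, partial response at
least a 30% decrease, complete response a drop below the imaging
detection limit, and stable disease anything in between.  Progression
(the PFS event) is the first time the targeted lesion meets the PD rule
against its own baseline; distant metastasis is the first time the
non-targeted lesion exceeds the 0.1 cc detection limit.  No death
process exists in the model, so patients without an event are censored
at the simulation horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .cohort import DM_DETECTION_CC
from .dynamics import Trajectory

DAYS_PER_MONTH = 365.25 / 12.0

PD_DIAMETER_RATIO = 1.2
PR_DIAMETER_RATIO = 0.7

#: PD on the diameter is equivalent to this factor on volume/cell count.
PD_VOLUME_RATIO = PD_DIAMETER_RATIO**3

#: Complete response: lesion below the 0.1 cc imaging detection limit.
DEFAULT_CR_THRESHOLD_CELLS = DM_DETECTION_CC * 1.0e9


class RecistCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class EventTime:
    """An event (or censoring) time in months."""

    time: float
    observed: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")


def volume_to_diameter(volume_cc: float | np.ndarray) -> float | np.ndarray:
    """Sphere-equivalent diameter (cm) of a volume (cc)."""
    v = np.asarray(volume_cc, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    out = np.cbrt(6.0 * v / math.pi)
    return float(out) if np.ndim(volume_cc) == 0 else out


def classify_recist(
    baseline_diam: float,
    current_diam: float,
    current_cells: float,
    cr_cell_threshold: float = DEFAULT_CR_THRESHOLD_CELLS,
) -> RecistCategory:
    """RECIST category from baseline/current longest diameters.

    Boundaries are inclusive ("at least" 30% decrease / 20% increase).
    CR takes precedence and is triggered by the cell count falling below
    the detection threshold.
    """
    if baseline_diam <= 0:
        raise ValueError("baseline diameter must be positive")
    if current_cells < cr_cell_threshold:
        return RecistCategory.CR
    if current_diam >= PD_DIAMETER_RATIO * baseline_diam:
        return RecistCategory.PD
    if current_diam <= PR_DIAMETER_RATIO * baseline_diam:
        return RecistCategory.PR
    return RecistCategory.SD


def classify_recist_cells(
    baseline_cells: np.ndarray,
    current_cells: np.ndarray,
    cr_cell_threshold: float = DEFAULT_CR_THRESHOLD_CELLS,
) -> np.ndarray:
    """Vectorized RECIST labels from cell counts (density cancels in the
    diameter ratio, which equals the cube root of the cell ratio)."""
    baseline_cells = np.asarray(baseline_cells, dtype=float)
    current_cells = np.asarray(current_cells, dtype=float)
    ratio = np.cbrt(current_cells / baseline_cells)
    # plain string labels (compare equal to the str-valued enum members)
    out = np.full(baseline_cells.shape, "SD", dtype="U2")
    out[ratio >= PD_DIAMETER_RATIO] = "PD"
    out[ratio <= PR_DIAMETER_RATIO] = "PR"
    out[current_cells < cr_cell_threshold] = "CR"
    return out


def _first_crossing_day(
    times: np.ndarray, values: np.ndarray, threshold: float
) -> float | None:
    """First day ``values`` reaches ``threshold`` from below (linear
    interpolation between samples); None if never."""
    if values[0] >= threshold:
        return float(times[0])
    above = values >= threshold
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    frac = (threshold - v0) / (v1 - v0)
    return float(t0 + frac * (t1 - t0))


def progression_time(traj: Trajectory, horizon: float) -> EventTime:
    """First time the targeted-tumor diameter is >= 1.2x baseline.

    ``horizon`` is in months; the returned time is in months, censored
    at the horizon when no progression occurs.
    """
    horizon_days = horizon * DAYS_PER_MONTH
    if traj.times[-1] + 1e-9 < horizon_days:
        raise ValueError("trajectory does not cover the requested horizon")
    threshold = PD_VOLUME_RATIO * traj.TI[0]
    day = _first_crossing_day(traj.times, traj.TI, threshold)
    if day is None or day > horizon_days:
        return EventTime(time=horizon, observed=False)
    return EventTime(time=day / DAYS_PER_MONTH, observed=True)


def dm_time(
    traj: Trajectory,
    horizon: float,
    threshold_cc: float = DM_DETECTION_CC,
    tumor_density: float = 1.0e9,
) -> EventTime:
    """First time the non-targeted tumor volume exceeds ``threshold_cc``.

    Patients whose non-targeted lesion is already detectable at baseline
    get the event at the first sampled time point.
    """
    horizon_days = horizon * DAYS_PER_MONTH
    if traj.times[-1] + 1e-9 < horizon_days:
        raise ValueError("trajectory does not cover the requested horizon")
    threshold = threshold_cc * tumor_density
    day = _first_crossing_day(traj.times, traj.TNI, threshold)
    if day is None or day > horizon_days:
        return EventTime(time=horizon, observed=False)
    return EventTime(time=day / DAYS_PER_MONTH, observed=True)


def crossing_days_to_event_times(
    days: np.ndarray, horizon_months: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert first-crossing days (NaN = never) to (months, observed)."""
    days = np.asarray(days, dtype=float)
    observed = ~np.isnan(days)
    months = np.where(observed, days / DAYS_PER_MONTH, horizon_months)
    months = np.minimum(months, horizon_months)
    observed = observed & (days / DAYS_PER_MONTH <= horizon_months)
    months = np.where(observed, months, horizon_months)
    return months, observed
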