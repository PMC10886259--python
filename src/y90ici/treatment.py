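"""Treatment plans: Y90 decay-fractionated radiation and ICI dosing.

Y90 radioembolization deposits its dose continuously with the 2.6-day
radioactive decay; the simulator represents it as a train of daily
instantaneous radiation events whose physical doses follow the decay
curve and sum exactly to the prescription.  The immune checkpoint
inhibitor (durvalumab) enters the dynamics only through a multiplicative
boost of the immune kill rate that decays with the drug's half-life and
is refreshed at every administration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .parameters import ModelParameters

ARM_LABELS = ("Y90_mono", "ICI_mono", "A", "B", "C")

#: Default number of daily Y90 fractions (10 half-lives, >99.9% of decay).
DEFAULT_N_FRACTIONS = 26

#: Default ICI course: one dose every 2 weeks for 2 years.
ICI_INTERVAL_DAYS = 14.0
ICI_DURATION_DAYS = 730.0

#: Fraction of each Y90 physical dose absorbed by circulating
#: lymphocytes transiting the perfused territory (free parameter).
DEFAULT_KAPPA_BLOOD = 0.05


@dataclass(frozen=True)
class RadiationEvent:
    """One instantaneous radiation delivery.

    ``d_tumor`` is the effective dose to the targeted tumor (already
    scaled by the patient's Y90 effectiveness q); ``d_physical`` is the
    unscaled physical dose of this fraction; ``d_lymph`` the dose to
    circulating lymphocytes.
    """

    time: float
    d_tumor: float
    d_lymph: float
    d_physical: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.d_tumor < 0 or self.d_lymph < 0 or self.d_physical < 0:
            raise ValueError("radiation doses must be non-negative")


@dataclass(frozen=True)
class TreatmentPlan:
    """Timed radiation events and ICI administrations for one arm."""

    radiation_events: tuple[RadiationEvent, ...]
    ici_dose_times: tuple[float, ...]
    delta_durva: float
    horizon: float
    arm_label: str = "A"

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise ValueError(
                f"unknown arm label {self.arm_label!r}; expected one of {ARM_LABELS}"
            )
        times = [ev.time for ev in self.radiation_events]
        if times != sorted(times):
            raise ValueError("radiation events must be time-ordered")

    @property
    def total_tumor_dose(self) -> float:
        return sum(ev.d_tumor for ev in self.radiation_events)

    @property
    def total_physical_dose(self) -> float:
        return sum(ev.d_physical for ev in self.radiation_events)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arm_label": self.arm_label,
            "delta_durva": self.delta_durva,
            "horizon": self.horizon,
            "radiation_events": [
                {
                    "time": ev.time,
                    "d_tumor": ev.d_tumor,
                    "d_lymph": ev.d_lymph,
                    "d_physical": ev.d_physical,
                }
                for ev in self.radiation_events
            ],
            "ici_dose_times": list(self.ici_dose_times),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TreatmentPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            radiation_events=tuple(
                RadiationEvent(**ev) for ev in payload["radiation_events"]
            ),
            ici_dose_times=tuple(payload["ici_dose_times"]),
            delta_durva=payload["delta_durva"],
            horizon=payload["horizon"],
            arm_label=payload["arm_label"],
        )


def y90_decay_weights(n_fractions: int, t_half: float) -> np.ndarray:
    """Per-day fractions of the total dose under exponential decay.

    Weight j integrates the decay curve over day j and is renormalized so
    the ``n_fractions`` weights sum to one.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    lam = math.log(2.0) / t_half
    j = np.arange(n_fractions)
    raw = np.exp(-lam * j) - np.exp(-lam * (j + 1))
    return raw / raw.sum()


def y90_schedule(
    total_physical_dose: float,
    start: float,
    q: float,
    p: ModelParameters,
    n_fractions: int = DEFAULT_N_FRACTIONS,
    kappa_blood: float = DEFAULT_KAPPA_BLOOD,
) -> list[RadiationEvent]:
    """Fractionate a Y90 prescription into daily decay-weighted events.

    Event j (day ``start + j``) carries physical dose
    ``total * (e^(-lambda j) - e^(-lambda (j+1))) / (1 - e^(-lambda n))``
    with ``lambda = ln2 / t_half_y90``; the normalization makes physical
    doses sum exactly to the prescription.  The effective tumor dose is
    ``q`` times the physical dose; lymphocytes receive ``kappa_blood``
    times the physical dose.
    """
    if total_physical_dose < 0:
        raise ValueError("total_physical_dose must be >= 0")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    weights = y90_decay_weights(n_fractions, p.t_half_y90)
    events = []
    for j, w in enumerate(weights):
        physical = total_physical_dose * float(w)
        events.append(
            RadiationEvent(
                time=start + j,
                d_tumor=q * physical,
                d_lymph=kappa_blood * physical,
                d_physical=physical,
            )
        )
    return events


_GBQ_TO_DIS_PER_S = 1.0e9
_S_PER_DAY = 86400.0


def dose_from_activity(A0: float, m: float, p: ModelParameters) -> float:
    """Absorbed dose (Gy) from an initial activity A0 (GBq) in mass m (kg).

    The cumulated activity of a fully decaying source is A0 * t_half/ln2;
    with the mean energy per transition absorbed locally and uniformly,
    dose = k * <E> * A0 * t_half / (ln2 * m) in consistent units.
    """
    if A0 < 0:
        raise ValueError("activity must be >= 0")
    if m <= 0:
        raise ValueError(f"absorbing mass must be > 0, got {m}")
    cumulated = A0 * _GBQ_TO_DIS_PER_S * p.t_half_y90 * _S_PER_DAY / math.log(2.0)
    return cumulated * p.E_mean * p.k / m


def ici_multiplier(
    t: float | np.ndarray,
    ici_dose_times: Sequence[float],
    delta_durva: float | np.ndarray,
    p: ModelParameters,
) -> float | np.ndarray:
    """Immune-kill multiplier omega1'(t)/omega1 under ICI therapy.

    Returns 1 before the first dose; afterwards
    ``1 + delta * C_max * exp(-ln2 (t - t_last)/t_half)`` with ``t_last``
    the most recent administration at or before ``t`` (the concentration
    resets to C_max at each dose).  Vectorized over ``t`` and/or
    ``delta_durva``.
    """
    decay = ici_concentration_factor(t, ici_dose_times, p)
    out = 1.0 + np.asarray(delta_durva) * p.C_max * decay
    if np.ndim(out) == 0:
        return float(out)
    return out


def ici_concentration_factor(
    t: float | np.ndarray,
    ici_dose_times: Sequence[float],
    p: ModelParameters,
) -> float | np.ndarray:
    """Normalized ICI concentration C(t)/C_max in [0, 1] (0 before dosing)."""
    times = np.asarray(ici_dose_times, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if times.size == 0:
        out = np.zeros_like(t_arr)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
    times = np.sort(times)
    idx = np.searchsorted(times, t_arr, side="right") - 1
    dosed = idx >= 0
    t_last = np.where(dosed, times[np.clip(idx, 0, None)], 0.0)
    decay = np.where(
        dosed, np.exp(-math.log(2.0) * (t_arr - t_last) / p.t_half_ici), 0.0
    )
    return float(decay) if np.isscalar(t) or t_arr.ndim == 0 else decay


def ici_course(
    start: float,
    interval: float = ICI_INTERVAL_DAYS,
    duration: float = ICI_DURATION_DAYS,
) -> tuple[float, ...]:
    """Administration days of a q2w ICI course covering ``duration`` days."""
    n = int(math.floor(duration / interval)) + 1
    return tuple(start + i * interval for i in range(n))


def build_arm_plan(
    arm: str,
    total_dose: float,
    delta_durva: float,
    interval: float,
    q: float,
    p: ModelParameters,
    horizon: float,
    n_fractions: int = DEFAULT_N_FRACTIONS,
    kappa_blood: float = DEFAULT_KAPPA_BLOOD,
) -> TreatmentPlan:
    """Build the treatment plan of one trial arm.

    Arm A delivers Y90 and starts the ICI course simultaneously at day 0;
    arm B delivers Y90 at day 0 and starts ICIs after ``interval`` days;
    arm C starts ICIs at day 0 and delivers Y90 after ``interval`` days.
    Monotherapy arms contain only their own modality.
    """
    if arm not in ARM_LABELS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARM_LABELS}")
    if interval < 0:
        raise ValueError("interval must be >= 0")

    y90_start: float | None
    ici_start: float | None
    if arm == "Y90_mono":
        y90_start, ici_start = 0.0, None
    elif arm == "ICI_mono":
        y90_start, ici_start = None, 0.0
    elif arm == "A":
        y90_start, ici_start = 0.0, 0.0
    elif arm == "B":
        y90_start, ici_start = 0.0, interval
    else:  # arm C
        y90_start, ici_start = interval, 0.0

    events: tuple[RadiationEvent, ...] = ()
    if y90_start is not None:
        events = tuple(
            y90_schedule(total_dose, y90_start, q, p, n_fractions, kappa_blood)
        )
    doses: tuple[float, ...] = ()
    if ici_start is not None:
        doses = ici_course(ici_start)
    return TreatmentPlan(
        radiation_events=events,
        ici_dose_times=doses,
        delta_durva=delta_durva if ici_start is not None else 0.0,
        horizon=horizon,
        arm_label=arm,
    )
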