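"""Continuous tumor-immune dynamics and event-driven integration.

Between radiation events the four compartments evolve continuously:

    dTI/dt  = a*TI  - omega1'(t) * TI  * L / (g + TI + TNI)
    dTNI/dt = a*TNI - omega1'(t) * TNI * L / (g + TI + TNI)
    dI/dt   = -r*I
    dL/dt   = omega2*(TI+TNI)*L/(g+TI+TNI) + omega3*I*L/(g+I) + s - f*L

with omega1'(t) = omega1 * (1 + delta_durva * C_max * C(t)/C_max) the
ICI-boosted immune kill rate.  Radiation cell kill is instantaneous at
the scheduled event times: the targeted tumor follows linear-quadratic
survival, killed cells move to the inactivated compartment, and
lymphocytes follow a linear survival model.  Non-targeted cells are
never irradiated.

The integrator is a fixed-step classical Runge-Kutta (RK4) scheme whose
step must divide the event times; it is vectorized across patients so a
whole cohort integrates in a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .treatment import TreatmentPlan, ici_concentration_factor


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite or strongly negative."""


@dataclass(frozen=True)
class SystemState:
    """State of the four compartments at time t (days)."""

    TI: float
    TNI: float
    I: float
    L: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("TI", "TNI", "I", "L"):
            if getattr(self, name) < 0:
                raise ValueError(f"compartment {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.TI, self.TNI, self.I, self.L], dtype=float)


@dataclass
class Trajectory:
    """Time series of the four compartments for one patient."""

    times: np.ndarray
    TI: np.ndarray
    TNI: np.ndarray
    I: np.ndarray
    L: np.ndarray
    events_applied: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.times)
        if any(len(x) != n for x in (self.TI, self.TNI, self.I, self.L)):
            raise ValueError("trajectory arrays must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def state_at(self, t: float) -> SystemState:
        """State at grid time t (linear interpolation between samples)."""
        TI = float(np.interp(t, self.times, self.TI))
        TNI = float(np.interp(t, self.times, self.TNI))
        I = float(np.interp(t, self.times, self.I))
        L = float(np.interp(t, self.times, self.L))
        return SystemState(TI=TI, TNI=TNI, I=I, L=L, t=t)

    def to_frame(self, patient_id: int | None = None, arm: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_d": self.times, "TI": self.TI, "TNI": self.TNI, "I": self.I, "L": self.L}
        )
        if patient_id is not None:
            df["patient_id"] = patient_id
        if arm is not None:
            df["arm"] = arm
        return df

    def to_csv(self, path: str | Path, patient_id: int | None = None, arm: str | None = None) -> None:
        self.to_frame(patient_id, arm).to_csv(path, index=False)


def _rates(TI, TNI, I, L, p: ModelParameters, mult):
    """Vectorized right-hand side; inputs already clipped at zero."""
    den = p.g + TI + TNI
    kill = p.omega1 * mult * L / den
    dTI = p.a * TI - kill * TI
    dTNI = p.a * TNI - kill * TNI
    dI = -p.r * I
    dL = (
        p.omega2 * (TI + TNI) * L / den
        + p.omega3 * I * L / (p.g + I)
        + p.s
        - p.f * L
    )
    return dTI, dTNI, dI, dL


def derivatives(
    state: SystemState, p: ModelParameters, ici_multiplier: float = 1.0
) -> tuple[float, float, float, float]:
    """Continuous part of the dynamics (radiation kill is event-based).

    ``ici_multiplier`` is omega1'(t)/omega1 >= 1 from the ICI model.
    """
    if min(state.TI, state.TNI, state.I, state.L) < 0:
        raise ValueError("state components must be non-negative")
    if ici_multiplier < 1.0:
        raise ValueError("ici_multiplier must be >= 1")
    d = _rates(state.TI, state.TNI, state.I, state.L, p, ici_multiplier)
    return tuple(float(x) for x in d)


def lq_survival(dose: float | np.ndarray, alpha: float | np.ndarray, alpha_beta_ratio: float):
    """Linear-quadratic surviving fraction exp(-alpha*d - beta*d^2)."""
    beta = alpha / alpha_beta_ratio
    return np.exp(-alpha * dose - beta * np.square(dose))


def apply_radiation_event(
    state: SystemState, d_tumor: float, d_lymph: float, p: ModelParameters
) -> SystemState:
    """Instantaneous radiation kill at one event.

    Targeted tumor cells survive with the LQ fraction; the killed cells
    move to the inactivated compartment (cell conservation is exact).
    Lymphocytes survive with exp(-alpha_L * d_lymph).  Non-targeted
    cells are outside the perfused territory and are unaffected.
    """
    if d_tumor < 0 or d_lymph < 0:
        raise ValueError("doses must be non-negative")
    sf = float(lq_survival(d_tumor, p.alpha_T, p.alpha_beta_ratio))
    killed = state.TI * (1.0 - sf)
    return SystemState(
        TI=state.TI * sf,
        TNI=state.TNI,
        I=state.I + killed,
        L=state.L * math.exp(-p.alpha_L * d_lymph),
        t=state.t,
    )


@dataclass
class CohortTrajectories:
    """Vectorized integration output for a batch of patients.

    ``progression_day`` / ``dm_day`` are first-crossing times (NaN when
    the threshold is never reached before the horizon); ``snapshots``
    maps a requested day to the (4, n) state array recorded there.
    """

    n: int
    horizon: float
    progression_day: np.ndarray
    dm_day: np.ndarray
    snapshots: dict[float, np.ndarray]
    final_state: np.ndarray
    times: np.ndarray | None = None
    states: np.ndarray | None = None  # (4, m, n) when recording requested


def _checked_alignment(value: float, dt: float, what: str) -> None:
    if abs(value / dt - round(value / dt)) > 1e-9:
        raise ValueError(f"{what} {value} is not a multiple of the step dt={dt}")


def simulate_cohort(
    initial: np.ndarray,
    plan: TreatmentPlan,
    p: ModelParameters,
    *,
    q: np.ndarray | float | None = None,
    alpha_T: np.ndarray | float | None = None,
    delta_durva: np.ndarray | float | None = None,
    dt: float = 0.25,
    horizon: float | None = None,
    progression_threshold: np.ndarray | None = None,
    dm_threshold: float | None = None,
    snapshot_days: Sequence[float] = (),
    record: bool = False,
    record_every: int | None = None,
) -> CohortTrajectories:
    """Integrate a batch of patients under one treatment plan.

    Parameters
    ----------
    initial : (4, n) array
        Rows TI, TNI, I, L at day 0 (pre-treatment baseline).
    q, alpha_T, delta_durva : arrays or scalars, optional
        Per-patient Y90 effectiveness, tumor radiosensitivity and ICI
        effectiveness.  When ``q`` is given, the tumor dose of every
        radiation event is ``q * d_physical`` of that event; otherwise
        the plan's pre-scaled ``d_tumor`` is used.  ``delta_durva``
        defaults to the plan's value.
    progression_threshold : (n,) array, optional
        Cell counts whose first upward crossing by TI is recorded.
    dm_threshold : float, optional
        Cell count whose first upward crossing by TNI is recorded.
    snapshot_days : days at which full states are stored (must lie on
        the grid).
    record : store the full trajectory every ``record_every`` steps
        (default: daily).
    """
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 2 or initial.shape[0] != 4:
        raise ValueError("initial must have shape (4, n)")
    if np.any(initial < 0):
        raise ValueError("initial state must be non-negative")
    n = initial.shape[1]
    horizon = plan.horizon if horizon is None else horizon
    if dt <= 0:
        raise ValueError("dt must be positive")
    _checked_alignment(horizon, dt, "horizon")
    for ev in plan.radiation_events:
        _checked_alignment(ev.time, dt, "radiation event time")
        if ev.time > horizon:
            raise ValueError(f"radiation event at day {ev.time} beyond horizon {horizon}")
    for day in snapshot_days:
        _checked_alignment(day, dt, "snapshot day")

    alpha = np.broadcast_to(
        np.asarray(p.alpha_T if alpha_T is None else alpha_T, dtype=float), (n,)
    ).copy()
    delta = np.broadcast_to(
        np.asarray(plan.delta_durva if delta_durva is None else delta_durva, dtype=float),
        (n,),
    ).copy()
    q_arr = None if q is None else np.broadcast_to(np.asarray(q, dtype=float), (n,)).copy()

    TI, TNI, I, L = (initial[i].copy() for i in range(4))
    scale = 1e-6 * (initial.sum(axis=0) + 1.0)

    n_steps = int(round(horizon / dt))
    # event bookkeeping: map step index -> list of events at that instant
    events_at: dict[int, list] = {}
    for ev in plan.radiation_events:
        events_at.setdefault(int(round(ev.time / dt)), []).append(ev)
    snap_steps = {int(round(day / dt)): float(day) for day in snapshot_days}

    prog_day = np.full(n, np.nan)
    dm_day = np.full(n, np.nan)
    track_prog = progression_threshold is not None
    track_dm = dm_threshold is not None
    if track_prog:
        prog_thr = np.asarray(progression_threshold, dtype=float)
        prog_day[TI >= prog_thr] = 0.0
    if track_dm:
        dm_day[TNI >= dm_threshold] = 0.0

    snapshots: dict[float, np.ndarray] = {}
    if 0 in snap_steps:
        snapshots[0.0] = np.stack([TI, TNI, I, L])

    if record_every is None:
        record_every = max(1, int(round(1.0 / dt)))
    rec_times: list[float] = []
    rec_states: list[np.ndarray] = []
    if record:
        rec_times.append(0.0)
        rec_states.append(np.stack([TI, TNI, I, L]))

    dose_times = plan.ici_dose_times

    def mult_at(t: float) -> np.ndarray | float:
        c = ici_concentration_factor(t, dose_times, p)
        return 1.0 + delta * p.C_max * c

    half = 0.5 * dt
    # overflow in a diverging state is detected explicitly, not warned
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        for k in range(n_steps + 1):
            t = k * dt
            # instantaneous radiation events at this instant
            for ev in events_at.get(k, ()):
                d_t = ev.d_tumor if q_arr is None else q_arr * ev.d_physical
                sf = lq_survival(d_t, alpha, p.alpha_beta_ratio)
                killed = TI * (1.0 - sf)
                TI = TI * sf
                I = I + killed
                L = L * math.exp(-p.alpha_L * ev.d_lymph)
            if k == n_steps:
                break

            m0 = mult_at(t)
            m1 = mult_at(t + half)
            m2 = mult_at(t + dt)

            k1 = _rates(TI, TNI, I, L, p, m0)
            a1 = (np.maximum(TI + half * k1[0], 0.0), np.maximum(TNI + half * k1[1], 0.0),
                  np.maximum(I + half * k1[2], 0.0), np.maximum(L + half * k1[3], 0.0))
            k2 = _rates(*a1, p, m1)
            a2 = (np.maximum(TI + half * k2[0], 0.0), np.maximum(TNI + half * k2[1], 0.0),
                  np.maximum(I + half * k2[2], 0.0), np.maximum(L + half * k2[3], 0.0))
            k3 = _rates(*a2, p, m1)
            a3 = (np.maximum(TI + dt * k3[0], 0.0), np.maximum(TNI + dt * k3[1], 0.0),
                  np.maximum(I + dt * k3[2], 0.0), np.maximum(L + dt * k3[3], 0.0))
            k4 = _rates(*a3, p, m2)

            sixth = dt / 6.0
            TI_new = TI + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            TNI_new = TNI + sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            I_new = I + sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            L_new = L + sixth * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])

            t_next = t + dt
            for name, arr in (("TI", TI_new), ("TNI", TNI_new), ("I", I_new), ("L", L_new)):
                if not np.all(np.isfinite(arr)):
                    raise IntegrationError(f"non-finite {name} at day {t_next:.3f}")
                low = arr < 0
                if np.any(low):
                    if np.any(arr[low] < -scale[low]):
                        raise IntegrationError(
                            f"{name} undershot below tolerance at day {t_next:.3f}"
                        )
                    arr[low] = 0.0

            if track_prog:
                crossing = np.isnan(prog_day) & (TI_new >= prog_thr) & (TI < prog_thr)
                if np.any(crossing):
                    frac = (prog_thr[crossing] - TI[crossing]) / (
                        TI_new[crossing] - TI[crossing]
                    )
                    prog_day[crossing] = t + frac * dt
            if track_dm:
                crossing = np.isnan(dm_day) & (TNI_new >= dm_threshold) & (TNI < dm_threshold)
                if np.any(crossing):
                    frac = (dm_threshold - TNI[crossing]) / (
                        TNI_new[crossing] - TNI[crossing]
                    )
                    dm_day[crossing] = t + frac * dt

            TI, TNI, I, L = TI_new, TNI_new, I_new, L_new

            step = k + 1
            if step in snap_steps:
                snapshots[snap_steps[step]] = np.stack([TI, TNI, I, L])
            if record and (step % record_every == 0 or step == n_steps):
                rec_times.append(step * dt)
                rec_states.append(np.stack([TI, TNI, I, L]))

    finally:
        np.seterr(**old_err)

    return CohortTrajectories(
        n=n,
        horizon=horizon,
        progression_day=prog_day,
        dm_day=dm_day,
        snapshots=snapshots,
        final_state=np.stack([TI, TNI, I, L]),
        times=np.asarray(rec_times) if record else None,
        states=np.stack(rec_states, axis=1) if record else None,
    )


def simulate(
    patient,
    plan: TreatmentPlan,
    p: ModelParameters,
    *,
    dt: float = 0.25,
    horizon: float | None = None,
    record_every: int | None = None,
) -> Trajectory:
    """Simulate a single patient and return the dense daily trajectory.

    ``patient`` may be a cohort Patient (sampled baseline and
    radiobiology) or a SystemState (population-mean parameters apply).
    """
    if isinstance(patient, SystemState):
        init = patient.as_array().reshape(4, 1)
        alpha, q_val, delta = p.alpha_T, None, None
    else:
        init = np.array(
            [[patient.T0], [patient.TNI0], [0.0], [patient.L0]], dtype=float
        )
        alpha, q_val, delta = patient.alpha_T, patient.q, None
        if plan.ici_dose_times:
            delta = plan.delta_durva

    res = simulate_cohort(
        init,
        plan,
        p,
        q=q_val,
        alpha_T=alpha,
        delta_durva=delta,
        dt=dt,
        horizon=horizon,
        record=True,
        record_every=record_every,
    )
    states = res.states[:, :, 0]
    return Trajectory(
        times=res.times,
        TI=states[0],
        TNI=states[1],
        I=states[2],
        L=states[3],
        events_applied=list(plan.radiation_events),
    )
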