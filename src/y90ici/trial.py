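"""Virtual clinical trial orchestration.

Runs the five treatment groups (Y90 monotherapy, ICI monotherapy and the
three combination arms A = concurrent, B = Y90 first, C = ICI first) on
one shared virtual cohort, converts trajectories to progression-free
survival (targeted lesion) and distant-metastasis (non-targeted lesion)
endpoints, and summarizes them with Kaplan-Meier curves, medians,
time-point rates and pairwise log-rank tests.  Sweeps repeat the same
machinery over a dose x ICI-effectiveness grid or over the
administration interval between the two modalities.

Common random numbers: the cohort (baselines, radiosensitivity, q,
delta) is sampled once and reused for every arm and every sweep cell,
so treatment contrasts are within-patient.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DM_DETECTION_CC, CohortSpec, sample_cohort_arrays
from .dynamics import IntegrationError, simulate_cohort
from .endpoints import DAYS_PER_MONTH, PD_VOLUME_RATIO, crossing_days_to_event_times
from .parameters import ModelParameters
from .survival import KMCurve, km_fit, logrank, rate_at
from .treatment import DEFAULT_KAPPA_BLOOD, build_arm_plan

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 120.0
DEFAULT_Y90_MONO_DOSE_GY = 400.0
RATE_YEARS = (1, 3, 5)


@dataclass(frozen=True)
class ArmSpec:
    """Dose and scheduling of one treatment group.

    ``label`` defaults to the arm name; give distinct labels to compare
    variants of the same arm within one trial.
    """

    arm: str
    dose: float = DEFAULT_Y90_MONO_DOSE_GY
    delta: float | None = None  # None -> per-patient sampled delta
    interval: float = 0.0
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label if self.label is not None else self.arm


def five_arm_specs(
    dose: float = DEFAULT_Y90_MONO_DOSE_GY,
    delta: float = 0.12,
    interval: float = 60.0,
    y90_mono_dose: float = DEFAULT_Y90_MONO_DOSE_GY,
) -> list[ArmSpec]:
    """The standard five treatment groups of the virtual trial."""
    return [
        ArmSpec("Y90_mono", dose=y90_mono_dose, delta=0.0),
        ArmSpec("ICI_mono", dose=0.0, delta=None),
        ArmSpec("A", dose=dose, delta=delta, interval=0.0),
        ArmSpec("B", dose=dose, delta=delta, interval=interval),
        ArmSpec("C", dose=dose, delta=delta, interval=interval),
    ]


@dataclass
class ArmResult:
    """Endpoints and survival summaries of one arm."""

    spec: ArmSpec
    events: pd.DataFrame  # patient_id, pfs_months, pfs_observed, dm_months, dm_observed
    km_pfs: KMCurve
    km_dm: KMCurve
    km_dm_evaluable: KMCurve | None
    n_excluded: int = 0

    @property
    def median_pfs(self) -> float:
        return self.km_pfs.median

    def pfs_rate(self, months: float):
        return rate_at(self.km_pfs, months)

    def dm_rate(self, months: float, evaluable_only: bool = False):
        curve = self.km_dm_evaluable if evaluable_only else self.km_dm
        return rate_at(curve, months, cumulative=True)

    def summary(self) -> dict:
        out = {
            "arm": self.spec.name,
            "dose_gy": self.spec.dose,
            "delta_durva": self.spec.delta,
            "interval_days": self.spec.interval,
            "n": int(len(self.events)),
            "median_pfs_months": self.median_pfs,
            "median_pfs_ci": list(self.km_pfs.median_ci),
        }
        for y in RATE_YEARS:
            r = self.pfs_rate(12.0 * y)
            out[f"pfs_{y}y_pct"] = 100.0 * r.rate
            out[f"pfs_{y}y_ci"] = [100.0 * r.ci_low, 100.0 * r.ci_high]
            d = self.dm_rate(12.0 * y)
            out[f"dm_{y}y_pct"] = 100.0 * d.rate
            out[f"dm_{y}y_ci"] = [100.0 * d.ci_low, 100.0 * d.ci_high]
        return out


@dataclass
class TrialResult:
    """Per-arm endpoints plus pairwise log-rank comparisons."""

    arms: dict[str, ArmResult]
    comparisons: pd.DataFrame  # arm_a, arm_b, endpoint, chi2, p
    horizon_months: float
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [res.summary() for res in self.arms.values()]
        ).set_index("arm")

    def event_table(self) -> pd.DataFrame:
        frames = []
        for label, res in self.arms.items():
            df = res.events.copy()
            df.insert(1, "arm", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _simulate_arm(
    arrays: Mapping[str, np.ndarray],
    spec: ArmSpec,
    p: ModelParameters,
    horizon_months: float,
    dt: float,
    kappa_blood: float,
    dm_threshold_cells: float,
    n_fractions: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Progression / DM crossing days for one arm (NaN = censored)."""
    n = len(arrays["T0"])
    horizon_days = round(horizon_months * DAYS_PER_MONTH / dt) * dt
    delta = arrays["delta_durva"] if spec.delta is None else spec.delta
    plan = build_arm_plan(
        spec.arm, spec.dose, 0.0 if spec.delta is None else spec.delta,
        spec.interval, 1.0, p,
        horizon=horizon_days, n_fractions=n_fractions, kappa_blood=kappa_blood,
    )
    init = np.stack([arrays["T0"], arrays["TNI0"], np.zeros(n), arrays["L0"]])
    kwargs = dict(
        q=arrays["q"], alpha_T=arrays["alpha_T"], delta_durva=delta,
        dt=dt, horizon=horizon_days,
        progression_threshold=PD_VOLUME_RATIO * arrays["T0"],
        dm_threshold=dm_threshold_cells,
    )
    try:
        res = simulate_cohort(init, plan, p, **kwargs)
        return res.progression_day, res.dm_day, 0
    except IntegrationError:
        # fall back to per-patient integration so isolated failures can
        # be excluded; abort when more than 1% of the cohort fails
        prog = np.full(n, np.nan)
        dm = np.full(n, np.nan)
        failed = np.zeros(n, dtype=bool)
        for i in range(n):
            sub = {
                k: (v[i : i + 1] if isinstance(v, np.ndarray) else v)
                for k, v in kwargs.items()
            }
            sub["progression_threshold"] = kwargs["progression_threshold"][i : i + 1]
            try:
                r = simulate_cohort(init[:, i : i + 1], plan, p, **sub)
                prog[i], dm[i] = r.progression_day[0], r.dm_day[0]
            except IntegrationError as exc:
                failed[i] = True
                logger.warning("patient %d excluded from arm %s: %s", i, spec.arm, exc)
        n_failed = int(failed.sum())
        if n_failed > 0.01 * n:
            raise IntegrationError(
                f"{n_failed}/{n} patients failed integration in arm {spec.arm}"
            )
        prog[failed] = np.nan  # excluded patients carry no events
        dm[failed] = np.nan
        return prog, dm, n_failed


def run_trial(
    cohort: Mapping[str, np.ndarray] | CohortSpec,
    arm_specs: Sequence[ArmSpec] | None = None,
    p: ModelParameters = ModelParameters(),
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    *,
    dt: float = 0.25,
    kappa_blood: float = DEFAULT_KAPPA_BLOOD,
    dm_threshold_cc: float = DM_DETECTION_CC,
    n_fractions: int = 26,
    seed: int | None = None,
) -> TrialResult:
    """Simulate every patient under every arm and summarize endpoints.

    ``cohort`` is either a sampled column view
    (:func:`y90ici.cohort.sample_cohort_arrays`) or a
    :class:`~y90ici.cohort.CohortSpec` to sample from.  DM curves are
    computed twice: over all patients (lesions already detectable at
    baseline count as events at time zero) and over the evaluable subset
    whose non-targeted lesion starts below the detection limit.
    """
    if isinstance(cohort, CohortSpec):
        seed = cohort.seed if seed is None else seed
        arrays = sample_cohort_arrays(cohort)
    else:
        arrays = cohort
    if arm_specs is None:
        arm_specs = five_arm_specs()
    dm_threshold_cells = dm_threshold_cc * p.tumor_density

    arms: dict[str, ArmResult] = {}
    for spec in arm_specs:
        prog_day, dm_day, n_excl = _simulate_arm(
            arrays, spec, p, horizon_months, dt, kappa_blood,
            dm_threshold_cells, n_fractions,
        )
        pfs_m, pfs_obs = crossing_days_to_event_times(prog_day, horizon_months)
        dm_m, dm_obs = crossing_days_to_event_times(dm_day, horizon_months)
        events = pd.DataFrame(
            {
                "patient_id": arrays["id"],
                "pfs_months": pfs_m,
                "pfs_observed": pfs_obs,
                "dm_months": dm_m,
                "dm_observed": dm_obs,
            }
        )
        evaluable = arrays["TNI0"] < dm_threshold_cells
        km_dm_eval = (
            km_fit(dm_m[evaluable], dm_obs[evaluable]) if np.any(evaluable) else None
        )
        arms[spec.name] = ArmResult(
            spec=spec,
            events=events,
            km_pfs=km_fit(pfs_m, pfs_obs),
            km_dm=km_fit(dm_m, dm_obs),
            km_dm_evaluable=km_dm_eval,
            n_excluded=n_excl,
        )

    rows = []
    for (la, ra), (lb, rb) in itertools.combinations(arms.items(), 2):
        for endpoint in ("pfs", "dm"):
            chi2, pval = logrank(
                ra.events[f"{endpoint}_months"], ra.events[f"{endpoint}_observed"],
                rb.events[f"{endpoint}_months"], rb.events[f"{endpoint}_observed"],
            )
            rows.append(
                {"arm_a": la, "arm_b": lb, "endpoint": endpoint, "chi2": chi2, "p": pval}
            )
    comparisons = pd.DataFrame(rows)

    return TrialResult(
        arms=arms,
        comparisons=comparisons,
        horizon_months=horizon_months,
        seed=seed,
        config={
            "dt": dt,
            "kappa_blood": kappa_blood,
            "dm_threshold_cc": dm_threshold_cc,
            "n_fractions": n_fractions,
            "arms": [vars(s) for s in arm_specs],
        },
    )


def dose_grid_sweep(
    cohort: Mapping[str, np.ndarray] | CohortSpec,
    doses: Sequence[float],
    deltas: Sequence[float],
    arms: Sequence[str] = ("A", "B", "C"),
    interval: float = 60.0,
    p: ModelParameters = ModelParameters(),
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Median PFS and 3-year DM rate over a dose x delta grid.

    Returns a tidy frame with one row per (dose, delta, arm) cell.
    """
    if len(doses) == 0 or len(deltas) == 0:
        raise ValueError("dose and delta grids must be non-empty")
    if isinstance(cohort, CohortSpec):
        seed = cohort.seed if seed is None else seed
        cohort = sample_cohort_arrays(cohort)
    rows = []
    for dose, delta in itertools.product(doses, deltas):
        specs = [ArmSpec(arm, dose=dose, delta=delta, interval=interval) for arm in arms]
        result = run_trial(
            cohort, specs, p, horizon_months, seed=seed, **kwargs
        )
        for label, res in result.arms.items():
            rows.append(
                {
                    "dose_gy": dose,
                    "delta_durva": delta,
                    "arm": label,
                    "median_pfs_months": res.median_pfs,
                    "dm3y_pct": 100.0 * res.dm_rate(36.0).rate,
                    "n": len(res.events),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


INTENSITY_PRESETS = {
    "min": (300.0, 0.08),
    "mid": (400.0, 0.12),
    "max": (500.0, 0.16),
}


def interval_sweep(
    cohort: Mapping[str, np.ndarray] | CohortSpec,
    intervals: Sequence[float],
    presets: Mapping[str, tuple[float, float]] = INTENSITY_PRESETS,
    p: ModelParameters = ModelParameters(),
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Arm B / C endpoints per administration interval, with arm A as the
    interval-independent concurrent reference."""
    if any(i < 0 or i > 300 for i in intervals):
        raise ValueError("intervals must lie in [0, 300] days")
    if isinstance(cohort, CohortSpec):
        seed = cohort.seed if seed is None else seed
        cohort = sample_cohort_arrays(cohort)
    rows = []
    for name, (dose, delta) in presets.items():
        ref = run_trial(
            cohort, [ArmSpec("A", dose=dose, delta=delta)], p,
            horizon_months, seed=seed, **kwargs,
        ).arms["A"]
        for interval in intervals:
            specs = [
                ArmSpec(arm, dose=dose, delta=delta, interval=interval)
                for arm in ("B", "C")
            ]
            result = run_trial(cohort, specs, p, horizon_months, seed=seed, **kwargs)
            for label, res in {**result.arms, "A": ref}.items():
                rows.append(
                    {
                        "intensity": name,
                        "dose_gy": dose,
                        "delta_durva": delta,
                        "interval_days": interval,
                        "arm": label,
                        "median_pfs_months": res.median_pfs,
                        "dm3y_pct": 100.0 * res.dm_rate(36.0).rate,
                        "n": len(res.events),
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
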