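"""Kaplan-Meier estimation and the two-sample log-rank test.

Thin survival-analysis layer over ``lifelines``: product-limit curves
with Greenwood variance, median survival (Brookmeyer-Crowley interval),
time-point rates with log-log (Kalbfleisch-Prentice) confidence limits,
and the standard 1-df log-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy.stats import norm


@dataclass
class KMCurve:
    """Product-limit estimate on the distinct event/censoring times."""

    event_times: np.ndarray      # distinct observed times (months)
    at_risk: np.ndarray          # subjects at risk just before each time
    events: np.ndarray           # events at each time
    survival: np.ndarray         # S(t) just after each time
    greenwood_var: np.ndarray    # Var[S(t)] by Greenwood's formula
    n: int
    median: float = np.nan       # NaN = not reached
    median_ci: tuple[float, float] = (np.nan, np.nan)
    _kmf: KaplanMeierFitter | None = field(default=None, repr=False, compare=False)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(self.greenwood_var)
        lo, hi = _loglog_ci(self.survival, self.greenwood_var)
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _loglog_ci(
    survival: np.ndarray, greenwood_var: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Kalbfleisch-Prentice limits exp(-exp(log(-log S) -/+ z*se_loglog))."""
    z = norm.ppf(0.5 + level / 2.0)
    s = np.clip(np.asarray(survival, dtype=float), 0.0, 1.0)
    lo = np.zeros_like(s)
    hi = np.ones_like(s)
    interior = (s > 0.0) & (s < 1.0)
    si = s[interior]
    se_ll = np.sqrt(greenwood_var[interior]) / np.abs(si * np.log(si))
    theta = np.log(-np.log(si))
    lo[interior] = np.exp(-np.exp(theta + z * se_ll))
    hi[interior] = np.exp(-np.exp(theta - z * se_ll))
    lo[s == 1.0] = 1.0
    hi[s == 0.0] = 0.0
    return lo, hi


def km_fit(times, observed) -> KMCurve:
    """Fit the Kaplan-Meier product-limit estimator.

    ``times`` are event/censoring times in months, ``observed`` marks
    events (True) vs censorings (False).  Ties are handled as
    simultaneous events at the shared time.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if times.size == 0:
        raise ValueError("cannot fit a survival curve to no subjects")
    if times.shape != observed.shape:
        raise ValueError("times and observed must have equal length")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    table = kmf.event_table  # every distinct time (event or censoring)
    t = table.index.to_numpy(dtype=float)
    keep = t > 0 if not np.any(times == 0.0) else np.ones_like(t, dtype=bool)
    t = t[keep]
    d = table["observed"].to_numpy(dtype=float)[keep]
    r = table["at_risk"].to_numpy(dtype=float)[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(np.where(r > 0, 1.0 - d / r, 1.0))
        # Greenwood: Var[S(t)] = S(t)^2 * sum d / (r (r - d))
        terms = np.where((r > 0) & (r > d), d / (r * (r - d)), 0.0)
        gvar = surv**2 * np.cumsum(terms)

    median = kmf.median_survival_time_
    median = float("nan") if np.isinf(median) else float(median)
    try:
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        lo = float("nan") if np.isinf(lo) else lo
        hi = float("nan") if np.isinf(hi) else hi
    except Exception:  # pragma: no cover - degenerate curves
        lo = hi = float("nan")

    return KMCurve(
        event_times=t,
        at_risk=r,
        events=d,
        survival=surv,
        greenwood_var=gvar,
        n=int(times.size),
        median=median,
        median_ci=(lo, hi),
        _kmf=kmf,
    )


def km_median(curve: KMCurve) -> float:
    """Smallest time with S(t) <= 0.5; NaN when the median is not reached."""
    return curve.median


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


def rate_at(curve: KMCurve, t: float, cumulative: bool = False) -> RateEstimate:
    """S(t) (or 1 - S(t) for cumulative incidence) with log-log 95% CI.

    Beyond the last follow-up time the last value is returned and the
    estimate flagged as extrapolated.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    extrapolated = curve.event_times.size > 0 and t > curve.event_times[-1]
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        s, var = 1.0, 0.0
    else:
        s = float(curve.survival[idx])
        var = float(curve.greenwood_var[idx])
    lo, hi = _loglog_ci(np.array([s]), np.array([var]))
    lo_v, hi_v = float(lo[0]), float(hi[0])
    if cumulative:
        return RateEstimate(1.0 - s, 1.0 - hi_v, 1.0 - lo_v, extrapolated)
    return RateEstimate(s, lo_v, hi_v, extrapolated)


def logrank(a_times, a_observed, b_times, b_observed) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    a_times = np.asarray(a_times, dtype=float)
    b_times = np.asarray(b_times, dtype=float)
    if a_times.size == 0 or b_times.size == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(
        a_times, b_times,
        event_observed_A=np.asarray(a_observed, dtype=bool),
        event_observed_B=np.asarray(b_observed, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)
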