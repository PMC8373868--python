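"""Cohort survival statistics: Kaplan-Meier, restricted mean, log-rank.

The product-limit estimator, the restricted mean survival time (the area
under the survival step function up to a horizon) and the two-group
log-rank test are implemented directly from their defining sums, so that
an external survival library can serve as an independent cross-check in
the test suite rather than as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "restricted_mean",
    "logrank_test",
    "mean_uncensored",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored event times: ``events[i]`` True = invasion observed."""

    times: np.ndarray
    events: np.ndarray

    def __init__(self, times: Sequence[float], events: Sequence[bool]) -> None:
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=bool)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d")
        if t.size == 0:
            raise ValueError("survival data must be non-empty")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function over the distinct event times.

    ``survival[j]`` is the estimate just after ``event_times[j]``; S(0)=1
    and the curve is constant between event times.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t): right-continuous step-function evaluation."""
        if self.event_times.size == 0:
            return 1.0 if np.isscalar(t) else np.ones_like(np.asarray(t, float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.maximum(idx, 0)])
        return float(s) if np.isscalar(t) else s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""

    statistic: float
    p_value: float


def km_estimate(data: SurvivalData) -> KMCurve:
    """Product-limit estimator with right censoring.

    Ties are grouped: at each distinct event time t with d events out of n
    at risk, the survival multiplies by (1 - d/n).  Subjects censored at t
    remain in the risk set at t (events precede censorings at ties).
    """
    order = np.argsort(data.times, kind="stable")
    times = data.times[order]
    events = data.events[order]
    n = times.size

    event_times = np.unique(times[events])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for j, t in enumerate(event_times):
        at_risk[j] = int(np.count_nonzero(times >= t))
        d[j] = int(np.count_nonzero((times == t) & events))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        event_times=event_times, at_risk=at_risk, events=d, survival=surv
    )


def restricted_mean(curve: KMCurve, horizon: float) -> float:
    """Area under the survival step function on [0, horizon].

    With no censoring and a horizon beyond the last event this equals the
    arithmetic mean of the event times.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return 0.0
    knots = np.concatenate(([0.0], np.minimum(curve.event_times, horizon), [horizon]))
    values = np.concatenate(([1.0], curve.survival))
    # survival value on [knots[j], knots[j+1]) is values[j]
    widths = np.diff(knots)
    return float(np.sum(widths * values[: widths.size]))


def mean_uncensored(data: SurvivalData) -> float:
    """Mean event time over uncensored subjects only (NaN if none)."""
    if not np.any(data.events):
        return float("nan")
    return float(data.times[data.events].mean())


def logrank_test(a: SurvivalData, b: SurvivalData) -> LogRankResult:
    """Standard two-group log-rank test (chi-square, 1 df).

    At each pooled distinct event time the observed events in group *a*
    are compared with their hypergeometric expectation under the null of
    identical hazards; an identically-zero variance (no comparable events)
    is signalled as an error.
    """
    pooled_times = np.concatenate([a.times, b.times])
    pooled_events = np.concatenate([a.events, b.events])
    if not np.any(pooled_events):
        raise ValueError("log-rank undefined: no events in either group")

    event_times = np.unique(pooled_times[pooled_events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int(np.count_nonzero(a.times >= t))
        n2 = int(np.count_nonzero(b.times >= t))
        d1 = int(np.count_nonzero((a.times == t) & a.events))
        d2 = int(np.count_nonzero((b.times == t) & b.events))
        nt = n1 + n2
        dt = d1 + d2
        if nt == 0 or dt == 0:
            continue
        o_minus_e += d1 - dt * n1 / nt
        if nt > 1:
            var += dt * (n1 / nt) * (n2 / nt) * (nt - dt) / (nt - 1)
    if var == 0.0:
        if o_minus_e == 0.0:
            return LogRankResult(statistic=0.0, p_value=1.0)
        raise ValueError("log-rank undefined: zero variance")
    stat = o_minus_e**2 / var
    return LogRankResult(
        statistic=float(stat), p_value=float(stats.chi2.sf(stat, df=1))
    )
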