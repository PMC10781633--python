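"""Kaplan–Meier product-limit estimation and endpoint summaries.

The product-limit estimator is the workhorse of the package: the
probability-of-being-in-response curve is the difference of two such curves,
and the companion endpoints (time to first response, duration of response,
failure-free survival) are ordinary KM summaries.

Conventions, chosen once for the whole package:

* ties between events and censorings at the same time are resolved
  events-first (the standard product-limit convention: a subject censored at
  ``t`` is still at risk for the events at ``t``);
* confidence intervals for ``S(t)`` use the complementary log-log transform
  with Greenwood variance, truncated to ``[0, 1]``;
* the median confidence interval is Brookmeyer–Crowley: invert the pointwise
  log-log interval of ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import NormalDist
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import FFS_EVENT_REASONS, RawSubject

__all__ = [
    "StepCurve",
    "ProbEstimate",
    "MedianEstimate",
    "km_fit",
    "km_prob_at",
    "km_median",
    "ffs_times",
]


@dataclass
class StepCurve:
    """A right-continuous piecewise-constant curve over time.

    ``estimate[i]`` is the value on ``[times[i], times[i+1])``; before
    ``times[0]`` the curve equals ``baseline`` (1 for survival curves, 0 for
    occupation and cumulative curves).  ``variance`` is the pointwise
    variance aligned to ``times`` (NaN where no variance estimate exists),
    and ``n_risk`` / ``n_event`` are the at-risk and event counts at each
    grid time.
    """

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    baseline: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.n_risk = np.asarray(self.n_risk)
        self.n_event = np.asarray(self.n_event)
        if not (
            self.times.shape == self.estimate.shape == self.variance.shape
            and self.times.shape == self.n_risk.shape == self.n_event.shape
        ):
            raise ValueError("StepCurve fields must share one grid")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def _lookup(self, values: np.ndarray, t, fill: float):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, fill)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            out = np.where(idx < 0, fill, values[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out

    def evaluate(self, t):
        """Right-continuous value at ``t`` (scalar or array)."""
        return self._lookup(self.estimate, t, self.baseline)

    def variance_at(self, t):
        return self._lookup(self.variance, t, 0.0)

    def to_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy export: time, estimate, std_err, lower, upper, n_risk, n_event."""
        lower = np.empty_like(self.estimate)
        upper = np.empty_like(self.estimate)
        for i, t in enumerate(self.times):
            _, lower[i], upper[i] = _loglog_ci(self.estimate[i], self.variance[i], alpha)
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "std_err": np.sqrt(np.where(np.isnan(self.variance), np.nan, self.variance)),
                "lower": lower,
                "upper": upper,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


@dataclass(frozen=True)
class ProbEstimate:
    estimate: float
    lower: float
    upper: float
    alpha: float = 0.05


@dataclass(frozen=True)
class MedianEstimate:
    """Median time with Brookmeyer–Crowley CI; None where undefined."""

    median: float | None
    lower: float | None
    upper: float | None
    alpha: float = 0.05


def km_fit(times: Iterable[float], events: Iterable[bool]) -> StepCurve:
    """Product-limit estimate of the survival function.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times,
    with Greenwood variance ``S(t)^2 * sum d_i / (n_i (n_i - d_i))``.  The
    grid holds event times only; censoring-only times affect the risk sets
    but add no grid point.
    """
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    e = np.asarray(list(events) if not isinstance(events, np.ndarray) else events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires at least one subject")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and nonnegative")

    uniq, inv = np.unique(t, return_inverse=True)
    d_all = np.bincount(inv, weights=e.astype(float)).astype(np.int64)
    removed = np.bincount(inv)
    at_risk_all = t.size - np.concatenate(([0], np.cumsum(removed)[:-1]))

    mask = d_all > 0
    if not np.any(mask):  # everyone censored: S identically 1
        return StepCurve(
            times=np.empty(0),
            estimate=np.empty(0),
            variance=np.empty(0),
            n_risk=np.empty(0, dtype=np.int64),
            n_event=np.empty(0, dtype=np.int64),
            baseline=1.0,
        )
    grid = uniq[mask]
    d = d_all[mask]
    n = at_risk_all[mask]
    surv = np.cumprod(1.0 - d / n)
    # Greenwood; the term is singular when everyone at risk dies, but there
    # S = 0 exactly and the variance is set to 0.
    with np.errstate(divide="ignore"):
        terms = np.where(n > d, d / (n * (n - d).astype(float)), np.inf)
    cum_terms = np.cumsum(terms)
    var = np.zeros_like(surv)
    positive = surv > 0.0
    var[positive] = surv[positive] ** 2 * cum_terms[positive]
    return StepCurve(times=grid, estimate=surv, variance=var, n_risk=n, n_event=d, baseline=1.0)


def _loglog_ci(s: float, var: float, alpha: float) -> tuple[float, float, float]:
    """Complementary log-log CI for a survival probability."""
    if np.isnan(var):
        return s, np.nan, np.nan
    if s <= 0.0:
        return 0.0, 0.0, 0.0
    if s >= 1.0:
        return 1.0, 1.0, 1.0
    z = NormalDist().inv_cdf(1.0 - alpha / 2.0)
    se_theta = np.sqrt(var) / (s * abs(np.log(s)))
    lower = s ** np.exp(z * se_theta)
    upper = s ** np.exp(-z * se_theta)
    return s, float(np.clip(lower, 0.0, 1.0)), float(np.clip(upper, 0.0, 1.0))


def km_prob_at(curve: StepCurve, t: float, alpha: float = 0.05) -> ProbEstimate:
    """Survival probability at ``t`` with a log-log Greenwood CI."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    s = curve.evaluate(t)
    var = curve.variance_at(t)
    est, lower, upper = _loglog_ci(float(s), float(var), alpha)
    return ProbEstimate(est, lower, upper, alpha)


def km_median(curve: StepCurve, alpha: float = 0.05) -> MedianEstimate:
    """Median survival time with Brookmeyer–Crowley confidence limits.

    The median is the smallest grid time with ``S(t) <= 0.5``; the interval
    collects the times whose pointwise log-log CI for ``S`` contains 0.5, so
    its lower limit is the first time the lower confidence curve reaches
    0.5 and its upper limit the first time the upper confidence curve does.
    Each is ``None`` when the relevant curve never reaches 0.5.
    """
    if curve.times.size == 0:
        return MedianEstimate(None, None, None, alpha)
    lower_ci = np.empty_like(curve.estimate)
    upper_ci = np.empty_like(curve.estimate)
    for i in range(curve.times.size):
        _, lower_ci[i], upper_ci[i] = _loglog_ci(curve.estimate[i], curve.variance[i], alpha)

    def _first_at_or_below(values: np.ndarray) -> float | None:
        hits = np.nonzero(values <= 0.5)[0]
        return float(curve.times[hits[0]]) if hits.size else None

    return MedianEstimate(
        median=_first_at_or_below(curve.estimate),
        lower=_first_at_or_below(lower_ci),
        upper=_first_at_or_below(upper_ci),
        alpha=alpha,
    )


def ffs_times(raws: Sequence[RawSubject]) -> tuple[np.ndarray, np.ndarray]:
    """Failure-free-survival input: time to relapse / new systemic therapy /
    death, whichever first, else censoring at last follow-up.

    Disease progression is *not* an FFS event; a subject whose only recorded
    terminal event is progression is censored at last follow-up.
    """
    times = np.empty(len(raws))
    events = np.empty(len(raws), dtype=bool)
    for i, r in enumerate(raws):
        if r.t_event is not None and r.event_reason in FFS_EVENT_REASONS:
            times[i], events[i] = r.t_event, True
        else:
            times[i], events[i] = r.t_last_followup, False
    return times, events
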