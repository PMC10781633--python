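"""Probability of being in response (PBR / PBIR) estimation.

The PBR at time ``t`` is the probability that a randomized subject occupies
the *in response* state of the progressive three-state model at ``t``.  It
aggregates two right-censored time-to-event variables — time from
randomization to first response (``u``) and time to entering the absorbing
state (``v``) — into a single curve defined on all randomized subjects:

    PBR(t) = g(t) - h(t)

where ``g`` is the product-limit survival curve of ``v`` (not yet absorbed)
and ``h`` the product-limit survival curve of ``u`` (still response-naive).
With no censoring this reduces exactly to the empirical fraction of subjects
in response at ``t``.

Pointwise uncertainty is quantified by a nonparametric bootstrap that
resamples subjects with replacement (arms independently for between-arm
difference curves).  The area under the PBR curve up to a horizon ``tau`` is
the expected duration of response (EDoR) restricted to ``tau``, in days.

Curves are *not* cut at the response window: responses are only counted up
to the window, while curves extend over the whole follow-up period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import MultistateSubject, RulesConfig
from .survival import MedianEstimate, StepCurve, km_fit, km_median

__all__ = [
    "PbrResult",
    "CurveBand",
    "TrialSummary",
    "pbr_estimate",
    "pbr_band",
    "pbr_difference",
    "edor",
    "cumulative_response",
    "trial_summary",
]

logger = logging.getLogger(__name__)

MIN_BOOTSTRAP = 100


def _as_arrays(subjects) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a list of MultistateSubject or a multistate-schema DataFrame."""
    if isinstance(subjects, pd.DataFrame):
        u = subjects["u_time"].to_numpy(dtype=float)
        ue = subjects["u_event"].to_numpy(dtype=bool)
        v = subjects["v_time"].to_numpy(dtype=float)
        ve = subjects["v_event"].to_numpy(dtype=bool)
    else:
        subjects = list(subjects)
        u = np.array([s.u_time for s in subjects], dtype=float)
        ue = np.array([s.u_event for s in subjects], dtype=bool)
        v = np.array([s.v_time for s in subjects], dtype=float)
        ve = np.array([s.v_event for s in subjects], dtype=bool)
    if u.size == 0:
        raise ValueError("at least one subject is required")
    return u, ue, v, ve


def _responded(subjects) -> np.ndarray:
    if isinstance(subjects, pd.DataFrame):
        return subjects["responded"].to_numpy(dtype=bool)
    return np.array([s.responded for s in subjects], dtype=bool)


@dataclass
class PbrResult:
    """PBR curve plus the two underlying product-limit curves.

    ``raw_difference`` keeps ``g - h`` before clipping negatives to zero, so
    the (rare) censoring-induced negative dips remain inspectable.
    """

    pbr: StepCurve
    h_curve: StepCurve
    g_curve: StepCurve
    raw_difference: np.ndarray
    n_subjects: int

    def evaluate(self, t):
        return self.pbr.evaluate(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.pbr.times,
                "estimate": self.pbr.estimate,
                "raw_difference": self.raw_difference,
                "n_risk": self.pbr.n_risk,
                "n_event": self.pbr.n_event,
            }
        )


@dataclass
class CurveBand:
    """A step curve with pointwise bootstrap confidence limits."""

    curve: StepCurve
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    method: str
    n_boot: int
    seed: int

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (self.lower.shape == self.upper.shape == self.curve.times.shape):
            raise ValueError("band limits must align with the curve grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.curve.times,
                "estimate": self.curve.estimate,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _km_eval(times: np.ndarray, events: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Survival probabilities at ``grid`` (fast path for bootstrap loops)."""
    uniq, inv = np.unique(times, return_inverse=True)
    d = np.bincount(inv, weights=events.astype(float))
    removed = np.bincount(inv)
    at_risk = times.size - np.concatenate(([0], np.cumsum(removed)[:-1]))
    mask = d > 0
    if not np.any(mask):
        return np.ones_like(grid, dtype=float)
    surv = np.cumprod(1.0 - d[mask] / at_risk[mask])
    idx = np.searchsorted(uniq[mask], grid, side="right") - 1
    return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, None)])


def _pbr_eval(u, ue, v, ve, grid) -> np.ndarray:
    return np.clip(_km_eval(v, ve, grid) - _km_eval(u, ue, grid), 0.0, 1.0)


def pbr_estimate(subjects) -> PbrResult:
    """Estimate the PBR curve for one cohort of multistate subjects.

    Negative values of ``g - h`` (possible under uneven censoring of the two
    underlying curves) are clipped to zero with a logged warning; the raw
    difference is retained on the result.
    """
    u, ue, v, ve = _as_arrays(subjects)
    h = km_fit(u, ue)
    g = km_fit(v, ve)
    grid = np.union1d(h.times, g.times)
    raw = g.evaluate(grid) - h.evaluate(grid) if grid.size else np.empty(0)
    if grid.size and np.any(raw < 0):
        logger.warning(
            "PBR estimate dipped below 0 (min %.3g) at %d grid point(s); clipped to 0",
            raw.min(),
            int(np.sum(raw < 0)),
        )
    estimate = np.clip(raw, 0.0, 1.0)

    # occupancy bookkeeping on the union grid: at risk of any transition,
    # and transitions (0->1, 0->2, 1->2) occurring at each grid time
    v_sorted = np.sort(v)
    n_risk = v.size - np.searchsorted(v_sorted, grid, side="left")
    resp = _responded(subjects)
    n_event = np.zeros(grid.size, dtype=np.int64)
    if grid.size:
        pos_u = np.searchsorted(grid, u[ue])
        valid = (pos_u < grid.size) & (grid[np.clip(pos_u, 0, grid.size - 1)] == u[ue])
        np.add.at(n_event, pos_u[valid], 1)
        loss = ve & resp
        pos_v = np.searchsorted(grid, v[loss])
        valid = (pos_v < grid.size) & (grid[np.clip(pos_v, 0, grid.size - 1)] == v[loss])
        np.add.at(n_event, pos_v[valid], 1)

    pbr_curve = StepCurve(
        times=grid,
        estimate=estimate,
        variance=np.full(grid.shape, np.nan),
        n_risk=n_risk,
        n_event=n_event,
        baseline=0.0,
    )
    return PbrResult(pbr=pbr_curve, h_curve=h, g_curve=g, raw_difference=raw, n_subjects=u.size)


def _check_bootstrap_args(n_boot: int, seed) -> None:
    if n_boot < MIN_BOOTSTRAP:
        raise ValueError(f"n_boot must be >= {MIN_BOOTSTRAP} for stable percentiles")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducible bootstrap bands")


def pbr_band(
    subjects,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> CurveBand:
    """Pointwise percentile-bootstrap confidence band for a single PBR curve.

    Subjects are resampled with replacement; each replicate's PBR is
    evaluated on the original estimate's jump grid (or on ``grid`` when
    given).  Deterministic for a fixed seed.
    """
    _check_bootstrap_args(n_boot, seed)
    u, ue, v, ve = _as_arrays(subjects)
    base = pbr_estimate(subjects)
    grid = base.pbr.times if grid is None else np.asarray(grid, dtype=float)
    estimate = base.pbr.evaluate(grid) if grid.size else np.empty(0)

    rng = np.random.default_rng(seed)
    n = u.size
    reps = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = _pbr_eval(u[idx], ue[idx], v[idx], ve[idx], grid)
    lower = np.minimum(np.quantile(reps, alpha / 2.0, axis=0), estimate)
    upper = np.maximum(np.quantile(reps, 1.0 - alpha / 2.0, axis=0), estimate)
    curve = StepCurve(
        times=grid,
        estimate=np.atleast_1d(estimate),
        variance=np.full(grid.shape, np.nan),
        n_risk=np.zeros(grid.shape, dtype=np.int64),
        n_event=np.zeros(grid.shape, dtype=np.int64),
        baseline=0.0,
    )
    return CurveBand(curve, lower, upper, alpha, "bootstrap_percentile", n_boot, seed)


def pbr_difference(
    arm_a_subjects,
    arm_b_subjects,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> CurveBand:
    """Between-arm PBR difference (first minus second) with pointwise CIs.

    The two arms are resampled independently in each bootstrap replicate.
    The default evaluation grid is the union of both arms' jump times.
    """
    _check_bootstrap_args(n_boot, seed)
    ua, uea, va, vea = _as_arrays(arm_a_subjects)
    ub, ueb, vb, veb = _as_arrays(arm_b_subjects)
    res_a = pbr_estimate(arm_a_subjects)
    res_b = pbr_estimate(arm_b_subjects)
    if grid is None:
        grid = np.union1d(res_a.pbr.times, res_b.pbr.times)
    else:
        grid = np.asarray(grid, dtype=float)
    estimate = np.atleast_1d(res_a.pbr.evaluate(grid) - res_b.pbr.evaluate(grid))

    rng = np.random.default_rng(seed)
    na, nb = ua.size, ub.size
    reps = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        reps[b] = _pbr_eval(ua[ia], uea[ia], va[ia], vea[ia], grid) - _pbr_eval(
            ub[ib], ueb[ib], vb[ib], veb[ib], grid
        )
    lower = np.minimum(np.quantile(reps, alpha / 2.0, axis=0), estimate)
    upper = np.maximum(np.quantile(reps, 1.0 - alpha / 2.0, axis=0), estimate)
    curve = StepCurve(
        times=grid,
        estimate=estimate,
        variance=np.full(grid.shape, np.nan),
        n_risk=np.zeros(grid.shape, dtype=np.int64),
        n_event=np.zeros(grid.shape, dtype=np.int64),
        baseline=0.0,
    )
    return CurveBand(curve, lower, upper, alpha, "bootstrap_percentile", n_boot, seed)


def edor(curve: StepCurve, tau: float) -> float:
    """Expected duration of response restricted to ``[0, tau]``, in days.

    Exact area of the step function (sum of rectangle areas, no quadrature).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    knots = np.concatenate(([0.0], curve.times))
    values = np.concatenate(([curve.baseline], curve.estimate))
    keep = knots < tau
    knots, values = knots[keep], values[keep]
    widths = np.diff(np.concatenate((knots, [tau])))
    return float(np.dot(values, widths))


def cumulative_response(subjects) -> StepCurve:
    """Cumulative proportion of subjects whose first response occurred by ``t``.

    The naive cumulation: it never decreases and deliberately ignores that a
    response may have been lost again; at and beyond the response window it
    equals the best-overall-response proportion.  Shown alongside PBR for
    comparison only.
    """
    u, ue, v, ve = _as_arrays(subjects)
    resp = _responded(subjects)
    n = u.size
    times = np.unique(u[resp])
    counts = np.array([np.sum(u[resp] <= t) for t in times], dtype=np.int64)
    n_event = np.concatenate(([counts[0]], np.diff(counts))) if times.size else counts
    return StepCurve(
        times=times,
        estimate=counts / n,
        variance=np.full(times.shape, np.nan),
        n_risk=np.full(times.shape, n, dtype=np.int64),
        n_event=n_event,
        baseline=0.0,
    )


@dataclass
class TrialSummary:
    """Response-endpoint summary for one cohort (typically one arm)."""

    n: int
    n_responders: int
    bor: float                     # best-overall-response proportion
    orr: float                     # proportion in response at orr_timepoint
    orr_timepoint: float
    ttfr_median: MedianEstimate    # time to first response, non-responders censored
    dor_curve: StepCurve | None    # KM of response duration, responders only


def trial_summary(
    subjects,
    rules: RulesConfig | None = None,
    orr_timepoint: float | None = None,
    alpha: float = 0.05,
) -> TrialSummary:
    """ORR / BOR / TTFR / DOR summary of a multistate cohort.

    BOR counts any response within the window regardless of when it occurred
    or whether it was later lost; ORR at a timepoint counts only subjects in
    state 1 at that time.  TTFR is a KM median over all subjects with
    non-responders censored at their leaving/censoring time; DOR is the KM
    curve of ``v - u`` on responders only.
    """
    rules = rules or RulesConfig()
    if orr_timepoint is None:
        orr_timepoint = rules.cutoff_days
    if orr_timepoint < 0:
        raise ValueError("orr_timepoint must be nonnegative")
    u, ue, v, ve = _as_arrays(subjects)
    resp = _responded(subjects)
    n = u.size
    n_resp = int(np.sum(resp))
    in_state1 = resp & (u <= orr_timepoint) & ~(ve & (v <= orr_timepoint))
    ttfr = km_median(km_fit(u, resp), alpha=alpha)
    dor_curve = km_fit(v[resp] - u[resp], ve[resp]) if n_resp else None
    return TrialSummary(
        n=n,
        n_responders=n_resp,
        bor=n_resp / n,
        orr=float(np.sum(in_state1)) / n,
        orr_timepoint=float(orr_timepoint),
        ttfr_median=ttfr,
        dor_curve=dor_curve,
    )
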