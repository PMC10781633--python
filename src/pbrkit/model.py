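"""Model/Results interface over the PBR machinery.

``PBRModel`` is built from subject-level data (a multistate DataFrame, a raw
timeline table, a CSV file, or a simulated trial); ``fit`` returns a
``PBRResults`` carrying per-arm curves, bootstrap bands, endpoint summaries
and a text ``summary()`` table, with plotting and export attached.

Typical use::

    model = PBRModel.from_raw_csv("trial.csv", rules=RulesConfig(cutoff_days=168))
    res = model.fit(n_boot=2000, seed=20)
    print(res.summary())
    diff = res.difference("active", "control", seed=21)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pbr as _pbr
from .events import (
    MultistateSubject,
    RawSubject,
    RulesConfig,
    derive_cohort,
    multistate_from_frame,
    multistate_to_frame,
    read_raw_csv,
)
from .markov import TrialConfig, simulate_trial
from .pbr import CurveBand, PbrResult, TrialSummary
from .survival import StepCurve

__all__ = ["PBRModel", "PBRResults"]


class PBRModel:
    """Probability-of-being-in-response model for a (multi-arm) cohort.

    Parameters
    ----------
    data
        Multistate records: a DataFrame in the multistate schema
        (``subject_id, arm, u_time, u_event, responded, v_time, v_event``)
        or a sequence of :class:`MultistateSubject`.
    rules
        Derivation rules (response window); kept for summaries.
    raw
        Optional raw-timeline records the multistate data was derived from
        (enables failure-free-survival summaries downstream).
    """

    def __init__(self, data, rules: RulesConfig | None = None, raw=None):
        if isinstance(data, pd.DataFrame):
            self.subjects = multistate_from_frame(data)
        else:
            self.subjects = list(data)
        if not self.subjects:
            raise ValueError("model requires at least one subject")
        self.rules = rules or RulesConfig()
        self.raw = list(raw) if raw is not None else None
        self.arms: list[str] = list(dict.fromkeys(s.arm for s in self.subjects))

    # ------------------------------------------------------------------
    @classmethod
    def from_raw(cls, raws, rules: RulesConfig | None = None) -> "PBRModel":
        """Build from raw timelines, applying the state-assignment rules."""
        rules = rules or RulesConfig()
        raws = list(raws)
        return cls(derive_cohort(raws, rules), rules=rules, raw=raws)

    @classmethod
    def from_raw_csv(cls, path, rules: RulesConfig | None = None) -> "PBRModel":
        return cls.from_raw(read_raw_csv(path), rules=rules)

    @classmethod
    def from_simulation(cls, config: TrialConfig) -> "PBRModel":
        multistates, raws = simulate_trial(config)
        rules = RulesConfig(cutoff_days=next(iter(config.arms.values())).cutoff_days)
        return cls(multistates, rules=rules, raw=raws)

    def to_frame(self) -> pd.DataFrame:
        """Multistate-schema DataFrame of the model's subjects."""
        return multistate_to_frame(self.subjects)

    # ------------------------------------------------------------------
    def _arm_subjects(self, arm: str) -> list[MultistateSubject]:
        subs = [s for s in self.subjects if s.arm == arm]
        if not subs:
            raise ValueError(f"unknown arm {arm!r}; available: {self.arms}")
        return subs

    def fit(
        self,
        alpha: float = 0.05,
        n_boot: int = 0,
        seed: int | None = None,
        orr_timepoint: float | None = None,
    ) -> "PBRResults":
        """Estimate per-arm PBR curves (with bootstrap bands if ``n_boot > 0``)."""
        results, bands, cumulative, summaries = {}, {}, {}, {}
        for arm in self.arms:
            subs = self._arm_subjects(arm)
            results[arm] = _pbr.pbr_estimate(subs)
            cumulative[arm] = _pbr.cumulative_response(subs)
            summaries[arm] = _pbr.trial_summary(
                subs, rules=self.rules, orr_timepoint=orr_timepoint, alpha=alpha
            )
            if n_boot > 0:
                bands[arm] = _pbr.pbr_band(subs, alpha=alpha, n_boot=n_boot, seed=seed)
        return PBRResults(
            model=self,
            results=results,
            bands=bands,
            cumulative=cumulative,
            summaries=summaries,
            alpha=alpha,
            n_boot=n_boot,
            seed=seed,
        )


@dataclass
class PBRResults:
    """Fitted per-arm PBR curves, bands, and endpoint summaries."""

    model: PBRModel
    results: dict[str, PbrResult]
    bands: dict[str, CurveBand]
    cumulative: dict[str, StepCurve]
    summaries: dict[str, TrialSummary]
    alpha: float
    n_boot: int
    seed: int | None

    @property
    def arms(self) -> list[str]:
        return self.model.arms

    # ------------------------------------------------------------------
    def pbr_at(self, arm: str, t) -> float:
        return self.results[arm].evaluate(t)

    def edor(self, tau: float) -> dict[str, float]:
        """Expected duration of response (days) restricted to ``[0, tau]``."""
        return {arm: _pbr.edor(r.pbr, tau) for arm, r in self.results.items()}

    def difference(
        self,
        treatment: str,
        reference: str,
        alpha: float | None = None,
        n_boot: int | None = None,
        seed: int | None = None,
        grid=None,
    ) -> CurveBand:
        """PBR difference curve (treatment minus reference) with pointwise CIs."""
        return _pbr.pbr_difference(
            self.model._arm_subjects(treatment),
            self.model._arm_subjects(reference),
            alpha=self.alpha if alpha is None else alpha,
            n_boot=(self.n_boot or 2000) if n_boot is None else n_boot,
            seed=self.seed if seed is None else seed,
            grid=grid,
        )

    def curve_frame(self, arm: str) -> pd.DataFrame:
        """Tidy per-arm curve: time, estimate (+ band limits if fitted)."""
        result = self.results[arm]
        frame = result.to_frame()
        if arm in self.bands:
            band = self.bands[arm]
            frame["lower"] = np.interp(
                frame["time"], band.curve.times, band.lower, left=0.0
            )
            frame["upper"] = np.interp(
                frame["time"], band.curve.times, band.upper, left=0.0
            )
        return frame

    # ------------------------------------------------------------------
    def summary(self, timepoints=(91.0, 182.0, 365.0)) -> str:
        """Endpoint-summary table, one column per arm.

        Reports N, best overall response, response proportion at the window,
        the median time to first response (non-responders censored) with its
        Brookmeyer–Crowley CI, PBR at the requested timepoints, and the
        restricted expected duration of response at the largest timepoint.
        """
        from .survival import km_prob_at

        arms = self.arms
        rows: list[tuple[str, list[str]]] = []
        rows.append(("N randomized", [f"{self.summaries[a].n}" for a in arms]))
        rows.append(
            ("Responders (BOR), n (%)",
             [f"{self.summaries[a].n_responders} ({100 * self.summaries[a].bor:.1f})"
              for a in arms])
        )
        rows.append(
            (f"In response at day {self.summaries[arms[0]].orr_timepoint:g} (%)",
             [f"{100 * self.summaries[a].orr:.1f}" for a in arms])
        )

        def fmt_median(m):
            if m.median is None:
                return "NR"
            lo = "NR" if m.lower is None else f"{m.lower:.1f}"
            hi = "NR" if m.upper is None else f"{m.upper:.1f}"
            return f"{m.median:.1f} ({lo}, {hi})"

        rows.append(
            ("TTFR median, d (95% CI)", [fmt_median(self.summaries[a].ttfr_median) for a in arms])
        )
        for t in timepoints:
            cells = []
            for a in arms:
                value = 100 * self.pbr_at(a, t)
                if a in self.bands:
                    band = self.bands[a]
                    idx = np.searchsorted(band.curve.times, t, side="right") - 1
                    if idx >= 0:
                        cells.append(
                            f"{value:.1f} ({100 * band.lower[idx]:.1f}, {100 * band.upper[idx]:.1f})"
                        )
                        continue
                cells.append(f"{value:.1f}")
            rows.append((f"PBR at day {t:g} (%)", cells))
        tau = max(timepoints)
        ed = self.edor(tau)
        rows.append((f"EDoR on [0, {tau:g}] (days)", [f"{ed[a]:.1f}" for a in arms]))

        label_w = max(len(r[0]) for r in rows)
        col_w = max(
            max((len(c) for _, cells in rows for c in cells), default=8),
            max(len(a) for a in arms),
        ) + 2
        lines = ["Probability-of-being-in-response summary", "=" * (label_w + col_w * len(arms))]
        lines.append(" " * label_w + "".join(a.rjust(col_w) for a in arms))
        lines.append("-" * (label_w + col_w * len(arms)))
        for label, cells in rows:
            lines.append(label.ljust(label_w) + "".join(c.rjust(col_w) for c in cells))
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot(self, ax=None, show_cumulative: bool = True):
        from .plotting import plot_pbr

        return plot_pbr(self.results, self.cumulative if show_cumulative else None, ax=ax)

    def plot_difference(self, treatment: str, reference: str, ax=None, **kwargs):
        from .plotting import plot_difference

        band = self.difference(treatment, reference, **kwargs)
        return plot_difference(band, ax=ax, label=f"{treatment} − {reference}")

    def to_frame(self) -> pd.DataFrame:
        return multistate_to_frame(self.model.subjects)
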