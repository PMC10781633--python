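"""Subject timelines and the progressive three-state response model.

A randomized subject starts in state 0 (*not in response*) at time 0
(randomization).  Achieving a first documented overall response moves the
subject to state 1 (*in response*).  State 2 is absorbing: it is entered on
death, start of a new systemic therapy, relapse of the underlying disease,
disease progression (responders only, ending the response), or — for
never-responders — at the response-window cut-off (week 24 by default), after
which a response can no longer be scored.  Transitions are progressive only
(0→1, 0→2, 1→2); a subject can never return to an earlier state.

This module converts raw per-subject timelines (:class:`RawSubject`) into the
two right-censored time-to-event variables that the probability-of-being-in-
response estimator consumes (:class:`MultistateSubject`):

``u``
    time of leaving state 0 — first response, direct absorption, or
    censoring while still response-naive;
``v``
    time of entering state 2 — loss of response / direct absorption, or
    censoring while in state 0 or 1.

Both CSV schemas (raw and derived) are round-trippable via the reader/writer
helpers at the bottom of the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EventReason",
    "FFS_EVENT_REASONS",
    "ValidationError",
    "RawSubject",
    "MultistateSubject",
    "RulesConfig",
    "Branch",
    "classify",
    "derive_multistate",
    "derive_cohort",
    "read_raw_csv",
    "raw_to_frame",
    "raw_from_frame",
    "multistate_to_frame",
    "multistate_from_frame",
]

#: Default response window: week 24 = 24 x 7 days.  The primary-endpoint visit
#: of a 28-day-cycle trial ("Cycle 7 Day 1") would be day 169; the window is a
#: config value so either convention is reproducible.
DEFAULT_CUTOFF_DAYS = 168.0


class EventReason(str, Enum):
    """Reason a subject entered the absorbing state (terminal event)."""

    DEATH = "death"
    NEW_SYSTEMIC_THERAPY = "new_systemic_therapy"
    RELAPSE = "relapse"
    #: progression of the disease under study; ends a response, but is *not*
    #: an absorbing trigger for a subject who never responded.
    PROGRESSION = "progression"


#: Terminal reasons that count as failure-free-survival events.  Progression
#: is deliberately excluded from FFS.
FFS_EVENT_REASONS = frozenset(
    {EventReason.DEATH, EventReason.NEW_SYSTEMIC_THERAPY, EventReason.RELAPSE}
)


class ValidationError(ValueError):
    """A subject record violates the timeline rules; names subject and rule."""

    def __init__(self, subject_id: str, rule: str):
        self.subject_id = subject_id
        self.rule = rule
        super().__init__(f"subject {subject_id!r}: {rule}")


@dataclass(frozen=True)
class RawSubject:
    """One subject's raw timeline, in days since randomization.

    ``t_event``/``event_reason`` describe the first terminal event, if any;
    ``t_last_followup`` is the last-contact / analysis-cutoff time and must
    dominate every other recorded time.
    """

    subject_id: str
    arm: str
    t_last_followup: float
    t_first_response: float | None = None
    t_event: float | None = None
    event_reason: EventReason | None = None

    def __post_init__(self):
        sid = self.subject_id
        if (self.t_event is None) != (self.event_reason is None):
            raise ValidationError(sid, "t_event and event_reason must be present together")
        for name in ("t_last_followup", "t_first_response", "t_event"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValidationError(sid, f"{name} must be finite and nonnegative, got {value}")
        if (
            self.t_first_response is not None
            and self.t_event is not None
            and self.t_first_response > self.t_event
        ):
            raise ValidationError(sid, "t_first_response must be <= t_event")
        latest = max(
            t for t in (self.t_first_response, self.t_event, 0.0) if t is not None
        )
        if self.t_last_followup < latest:
            raise ValidationError(sid, "t_last_followup must be >= every recorded time")
        if self.event_reason is EventReason.PROGRESSION and self.t_first_response is None:
            raise ValidationError(
                sid, "progression is not an absorbing trigger for a never-responder"
            )


@dataclass(frozen=True)
class MultistateSubject:
    """Derived multistate record: the (u, v) pair with censoring flags.

    Invariants (validated at construction): ``u_time <= v_time``;
    ``responded`` implies ``u_event``; no state-2 entry without leaving
    state 0; a never-responding leaver goes straight to state 2
    (``u_time == v_time`` with both events).
    """

    subject_id: str
    arm: str
    u_time: float
    u_event: bool
    responded: bool
    v_time: float
    v_event: bool

    def __post_init__(self):
        sid = self.subject_id
        if self.u_time < 0 or self.v_time < self.u_time:
            raise ValidationError(sid, "times must satisfy 0 <= u_time <= v_time")
        if self.responded and not self.u_event:
            raise ValidationError(sid, "responded implies u_event")
        if self.v_event and not self.u_event:
            raise ValidationError(sid, "cannot enter state 2 without leaving state 0")
        if self.u_event and not self.responded:
            if not (self.v_event and self.v_time == self.u_time):
                raise ValidationError(
                    sid, "a never-responder leaving state 0 must absorb at the same time"
                )
        if not self.u_event and self.v_time != self.u_time:
            raise ValidationError(sid, "censored in state 0 requires u_time == v_time")


@dataclass(frozen=True)
class RulesConfig:
    """Event-derivation rules: response window and optional analysis cutoff."""

    cutoff_days: float = DEFAULT_CUTOFF_DAYS
    analysis_cutoff_days: float | None = None

    def __post_init__(self):
        if not self.cutoff_days > 0:
            raise ValueError(f"cutoff_days must be > 0, got {self.cutoff_days}")
        if self.analysis_cutoff_days is not None and self.analysis_cutoff_days <= 0:
            raise ValueError("analysis_cutoff_days must be > 0 when given")


class Branch(str, Enum):
    """The five mutually exclusive derivation outcomes."""

    RESPONDER_EVENT = "responder_event"          # 0→1 then 1→2 observed
    RESPONDER_CENSORED = "responder_censored"    # 0→1, censored in state 1
    DIRECT_ABSORPTION = "direct_absorption"      # 0→2 on a terminal event
    WINDOW_ABSORPTION = "window_absorption"      # 0→2 at the cut-off, no response
    CENSORED_STATE0 = "censored_state0"          # lost before the cut-off


def _truncate(raw: RawSubject, analysis_cutoff: float | None) -> RawSubject:
    """Administratively censor a raw record at the analysis cutoff."""
    if analysis_cutoff is None or raw.t_last_followup <= analysis_cutoff:
        return raw
    resp = raw.t_first_response
    if resp is not None and resp > analysis_cutoff:
        resp = None
    t_event, reason = raw.t_event, raw.event_reason
    if t_event is not None and t_event > analysis_cutoff:
        t_event, reason = None, None
    return replace(
        raw,
        t_first_response=resp,
        t_event=t_event,
        event_reason=reason,
        t_last_followup=analysis_cutoff,
    )


def classify(raw: RawSubject, rules: RulesConfig) -> Branch:
    """Which of the five derivation branches applies to ``raw``."""
    raw = _truncate(raw, rules.analysis_cutoff_days)
    c = rules.cutoff_days
    if raw.t_first_response is not None:
        if raw.t_first_response > c:
            raise ValidationError(
                raw.subject_id,
                f"first response at {raw.t_first_response} is after the "
                f"response window ({c} d); pre-truncate the record",
            )
        return Branch.RESPONDER_EVENT if raw.t_event is not None else Branch.RESPONDER_CENSORED
    if raw.event_reason is EventReason.PROGRESSION:  # unreachable via RawSubject, kept for frames
        raise ValidationError(
            raw.subject_id, "progression is not an absorbing trigger for a never-responder"
        )
    if raw.t_event is not None and raw.t_event <= c:
        return Branch.DIRECT_ABSORPTION
    if raw.t_last_followup >= c:
        return Branch.WINDOW_ABSORPTION
    return Branch.CENSORED_STATE0


def derive_multistate(raw: RawSubject, rules: RulesConfig | None = None) -> MultistateSubject:
    """Map a raw timeline onto the three-state model.

    Branches, applied in order:

    * a first response at ``t <= cutoff_days`` puts the subject in state 1 at
      ``t``; a response recorded after the window is a validation error;
    * a responder absorbs (state 2) at the terminal-event time if one is
      recorded, otherwise is censored in state 1 at last follow-up;
    * a never-responder with a terminal event at or before the cut-off goes
      0→2 at that time (a terminal event exactly at the cut-off is taken as
      the informative trigger);
    * a never-responder followed to the cut-off with no terminal event before
      it absorbs at the cut-off (the week-24 rule);
    * a never-responder lost before the cut-off is censored in state 0.
    """
    rules = rules or RulesConfig()
    raw = _truncate(raw, rules.analysis_cutoff_days)
    branch = classify(raw, rules)
    c = rules.cutoff_days
    sid, arm, fup = raw.subject_id, raw.arm, raw.t_last_followup

    if branch is Branch.RESPONDER_EVENT:
        return MultistateSubject(sid, arm, raw.t_first_response, True, True, raw.t_event, True)
    if branch is Branch.RESPONDER_CENSORED:
        return MultistateSubject(sid, arm, raw.t_first_response, True, True, fup, False)
    if branch is Branch.DIRECT_ABSORPTION:
        t = raw.t_event
        return MultistateSubject(sid, arm, t, True, False, t, True)
    if branch is Branch.WINDOW_ABSORPTION:
        return MultistateSubject(sid, arm, c, True, False, c, True)
    return MultistateSubject(sid, arm, fup, False, False, fup, False)


def derive_cohort(
    raws: Iterable[RawSubject], rules: RulesConfig | None = None
) -> list[MultistateSubject]:
    rules = rules or RulesConfig()
    return [derive_multistate(r, rules) for r in raws]


# ---------------------------------------------------------------------------
# CSV / DataFrame interchange

RAW_COLUMNS = ["subject_id", "arm", "t_first_response", "t_event", "event_reason", "t_last_followup"]
MULTISTATE_COLUMNS = ["subject_id", "arm", "u_time", "u_event", "responded", "v_time", "v_event"]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def raw_from_frame(frame: pd.DataFrame) -> list[RawSubject]:
    """Build :class:`RawSubject` records from a raw-schema DataFrame."""
    missing = [c for c in RAW_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"raw table is missing columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        reason = getattr(row, "event_reason")
        if reason is None or (isinstance(reason, float) and math.isnan(reason)) or reason == "":
            reason_enum = None
        else:
            try:
                reason_enum = EventReason(str(reason))
            except ValueError as exc:
                raise ValidationError(
                    str(row.subject_id), f"unknown event_reason {reason!r}"
                ) from exc
        out.append(
            RawSubject(
                subject_id=str(row.subject_id),
                arm=str(row.arm),
                t_last_followup=float(row.t_last_followup),
                t_first_response=_opt(row.t_first_response),
                t_event=_opt(row.t_event),
                event_reason=reason_enum,
            )
        )
    return out


def read_raw_csv(path: str | Path) -> list[RawSubject]:
    frame = pd.read_csv(path, dtype={"subject_id": str, "arm": str, "event_reason": str})
    return raw_from_frame(frame)


def raw_to_frame(raws: Sequence[RawSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in raws],
            "arm": [r.arm for r in raws],
            "t_first_response": [r.t_first_response for r in raws],
            "t_event": [r.t_event for r in raws],
            "event_reason": [r.event_reason.value if r.event_reason else None for r in raws],
            "t_last_followup": [r.t_last_followup for r in raws],
        }
    )[RAW_COLUMNS]


def multistate_to_frame(subjects: Sequence[MultistateSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "arm": [s.arm for s in subjects],
            "u_time": [s.u_time for s in subjects],
            "u_event": [s.u_event for s in subjects],
            "responded": [s.responded for s in subjects],
            "v_time": [s.v_time for s in subjects],
            "v_event": [s.v_event for s in subjects],
        }
    )[MULTISTATE_COLUMNS]


def multistate_from_frame(frame: pd.DataFrame) -> list[MultistateSubject]:
    missing = [c for c in MULTISTATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"multistate table is missing columns: {missing}")
    return [
        MultistateSubject(
            subject_id=str(row.subject_id),
            arm=str(row.arm),
            u_time=float(row.u_time),
            u_event=bool(row.u_event),
            responded=bool(row.responded),
            v_time=float(row.v_time),
            v_event=bool(row.v_event),
        )
        for row in frame.itertuples(index=False)
    ]
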