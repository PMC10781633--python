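"""Shared fixtures and data builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pbrkit import (
    EventReason,
    MultistateSubject,
    RawSubject,
    RulesConfig,
)


@pytest.fixture
def rules() -> RulesConfig:
    return RulesConfig(cutoff_days=168.0)


def ms(u, ue, resp, v, ve, sid="s", arm="a") -> MultistateSubject:
    """Terse MultistateSubject builder for hand-crafted datasets."""
    return MultistateSubject(
        subject_id=sid, arm=arm, u_time=float(u), u_event=bool(ue),
        responded=bool(resp), v_time=float(v), v_event=bool(ve),
    )


def uncensored_cohort(rng: np.random.Generator, n: int, arm: str = "a"):
    """A fully observed cohort: responders with a loss time, or direct absorbers."""
    responded = rng.random(n) < 0.5
    u = np.round(rng.random(n) * 100, 3)
    duration = np.round(rng.random(n) * 80, 3)
    v = np.where(responded, u + duration, u)
    subjects = [
        ms(u[i], True, responded[i], v[i], True, sid=f"{arm}{i}", arm=arm)
        for i in range(n)
    ]
    return subjects, u, v, responded


@pytest.fixture
def seven_patients() -> list[RawSubject]:
    """A seven-subject raw cohort exercising every derivation branch.

    Responder still in response at analysis; responders who lost response
    (progression / new therapy / death); a never-responder dying without
    response; a never-responder passing the window without response; and a
    never-responder lost before the window.
    """
    return [
        RawSubject("p1", "a", t_last_followup=500.0, t_first_response=25.0),
        RawSubject("p2", "a", 300.0, 40.0, 210.0, EventReason.PROGRESSION),
        RawSubject("p3", "a", 120.0, 30.0, 120.0, EventReason.NEW_SYSTEMIC_THERAPY),
        RawSubject("p4", "b", 400.0),                               # window absorption
        RawSubject("p5", "b", 55.0, None, 55.0, EventReason.DEATH),  # died without response
        RawSubject("p6", "b", 250.0, 20.0, 90.0, EventReason.DEATH),
        RawSubject("p7", "b", 100.0),                               # lost before the window
    ]
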