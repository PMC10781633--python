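"""The PBR estimator, bootstrap bands, EDoR, cumulative responders, summaries."""

from __future__ import annotations

import numpy as np
import pytest

from pbrkit import (
    StepCurve,
    cumulative_response,
    edor,
    pbr_band,
    pbr_difference,
    pbr_estimate,
    trial_summary,
)

from conftest import ms, uncensored_cohort


def step(times, values, baseline=0.0) -> StepCurve:
    times = np.asarray(times, dtype=float)
    return StepCurve(
        times=times,
        estimate=np.asarray(values, dtype=float),
        variance=np.full(times.shape, np.nan),
        n_risk=np.zeros(times.shape, dtype=int),
        n_event=np.zeros(times.shape, dtype=int),
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
def test_two_subject_fractions():
    # A responds at 10, loses at 30; B absorbs directly at 20
    subjects = [ms(10, True, True, 30, True), ms(20, True, False, 20, True)]
    res = pbr_estimate(subjects)
    for t, expected in [(5, 0.0), (10, 0.5), (19, 0.5), (25, 0.5), (30, 0.0), (100, 0.0)]:
        assert res.evaluate(t) == pytest.approx(expected, abs=1e-12)
    assert res.pbr.baseline == 0.0


def test_no_responders_gives_zero_curve():
    subjects = [ms(t, True, False, t, True) for t in (5.0, 10.0, 20.0)]
    res = pbr_estimate(subjects)
    assert np.all(res.pbr.estimate == pytest.approx(0.0, abs=1e-12))


def test_censored_cohort_matches_hand_product_limit():
    """Four subjects, one censored in each state; hand-derived g and h values.

    h events at 10, 15, 20 with risk sets 4, 3, 2 -> 3/4, 1/2, 1/4.
    g events at 15, 50 with risk sets 4, 2 -> 3/4, 3/8.
    """
    subjects = [
        ms(10, True, True, 50, True),    # responder, loses response at 50
        ms(20, True, True, 60, False),   # responder, censored in state 1
        ms(15, True, False, 15, True),   # direct absorption
        ms(30, False, False, 30, False), # censored in state 0
    ]
    res = pbr_estimate(subjects)
    expected = {10.0: 1 - 3 / 4, 15.0: 3 / 4 - 1 / 2, 20.0: 3 / 4 - 1 / 4, 50.0: 3 / 8 - 1 / 4}
    for t, val in expected.items():
        assert res.evaluate(t) == pytest.approx(val, abs=1e-12)
    np.testing.assert_allclose(res.raw_difference, np.clip(res.raw_difference, None, None))


def test_uncensored_counting_property():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(2, 40))
        subjects, u, v, resp = uncensored_cohort(rng, n)
        res = pbr_estimate(subjects)
        for t in res.pbr.times:
            counted = np.sum(resp & (u <= t) & (t < v)) / n
            assert res.evaluate(t) == pytest.approx(counted, abs=1e-12)


def test_pbr_bounded_below_cumulative_curve():
    rng = np.random.default_rng(5)
    subjects, *_ = uncensored_cohort(rng, 60)
    res = pbr_estimate(subjects)
    cum = cumulative_response(subjects)
    grid = np.union1d(res.pbr.times, cum.times)
    assert np.all(res.pbr.evaluate(grid) <= cum.evaluate(grid) + 1e-12)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        pbr_estimate([])


# ---------------------------------------------------------------------------
def test_edor_rectangle_and_zero():
    curve = step([10.0, 30.0], [0.5, 0.0])
    assert edor(curve, 40.0) == pytest.approx(10.0)
    assert edor(step([5.0], [0.0]), 100.0) == 0.0
    with pytest.raises(ValueError):
        edor(curve, 0.0)


def test_edor_truncated_mean_on_uncensored_data():
    rng = np.random.default_rng(9)
    subjects, u, v, resp = uncensored_cohort(rng, 50)
    res = pbr_estimate(subjects)
    for tau in (30.0, 80.0, 200.0):
        per_subject = np.where(resp, np.clip(np.minimum(v, tau) - np.minimum(u, tau), 0, None), 0.0)
        assert edor(res.pbr, tau) == pytest.approx(per_subject.mean(), abs=1e-9)


def test_edor_additivity():
    rng = np.random.default_rng(13)
    subjects, *_ = uncensored_cohort(rng, 30)
    curve = pbr_estimate(subjects).pbr
    t1, t2 = 40.0, 120.0
    # independent area on [t1, t2] by direct rectangle summation
    knots = np.concatenate(([0.0], curve.times))
    values = np.concatenate(([curve.baseline], curve.estimate))
    grid = np.unique(np.concatenate((knots[(knots > t1) & (knots < t2)], [t1, t2])))
    heights = values[np.searchsorted(knots, grid[:-1], side="right") - 1]
    middle = float(np.dot(heights, np.diff(grid)))
    assert edor(curve, t1) + middle == pytest.approx(edor(curve, t2), abs=1e-9)


# ---------------------------------------------------------------------------
def test_cumulative_response_counts():
    subjects = [
        ms(10, True, True, 40, True), ms(20, True, True, 70, False),
        ms(5, True, False, 5, True), ms(30, False, False, 30, False),
    ]
    cum = cumulative_response(subjects)
    assert cum.evaluate(9.0) == 0.0
    assert cum.evaluate(10.0) == 0.25
    assert cum.evaluate(20.0) == 0.5
    assert cum.evaluate(1000.0) == 0.5  # final value = BOR proportion

    none = cumulative_response([ms(5, True, False, 5, True)])
    assert none.times.size == 0 and none.evaluate(50.0) == 0.0


# ---------------------------------------------------------------------------
def test_bootstrap_band_deterministic_and_bounded():
    rng = np.random.default_rng(21)
    subjects, *_ = uncensored_cohort(rng, 40)
    band1 = pbr_band(subjects, n_boot=200, seed=42)
    band2 = pbr_band(subjects, n_boot=200, seed=42)
    np.testing.assert_array_equal(band1.lower, band2.lower)
    np.testing.assert_array_equal(band1.upper, band2.upper)
    assert np.all(band1.lower >= 0.0) and np.all(band1.upper <= 1.0)
    assert np.all(band1.lower <= band1.curve.estimate)
    assert np.all(band1.curve.estimate <= band1.upper)


def test_bootstrap_band_single_subject_degenerates():
    band = pbr_band([ms(10, True, True, 30, True)], n_boot=150, seed=1)
    np.testing.assert_array_equal(band.lower, band.curve.estimate)
    np.testing.assert_array_equal(band.upper, band.curve.estimate)


def test_bootstrap_requires_enough_replicates_and_a_seed():
    subjects = [ms(10, True, True, 30, True), ms(20, True, False, 20, True)]
    with pytest.raises(ValueError, match="n_boot"):
        pbr_band(subjects, n_boot=50, seed=1)
    with pytest.raises(ValueError, match="seed"):
        pbr_band(subjects, n_boot=200)


def test_identical_arms_difference_is_zero():
    rng = np.random.default_rng(31)
    subjects, *_ = uncensored_cohort(rng, 30)
    band = pbr_difference(subjects, subjects, n_boot=200, seed=5)
    np.testing.assert_array_equal(band.curve.estimate, np.zeros_like(band.curve.estimate))
    assert np.all(band.lower <= 0.0) and np.all(band.upper >= 0.0)


def test_difference_against_nonresponding_arm_equals_pbr():
    rng = np.random.default_rng(37)
    arm_a, *_ = uncensored_cohort(rng, 30)
    arm_b = [ms(t, True, False, t, True, arm="b") for t in np.linspace(5, 150, 20)]
    band = pbr_difference(arm_a, arm_b, n_boot=150, seed=6)
    res_a = pbr_estimate(arm_a)
    np.testing.assert_allclose(
        band.curve.estimate, res_a.evaluate(band.curve.times), atol=1e-12
    )


def test_difference_sign_convention():
    rng = np.random.default_rng(41)
    arm_a, *_ = uncensored_cohort(rng, 30)
    arm_b, *_ = uncensored_cohort(np.random.default_rng(42), 25)
    ab = pbr_difference(arm_a, arm_b, n_boot=150, seed=7)
    ba = pbr_difference(arm_b, arm_a, n_boot=150, seed=7, grid=ab.curve.times)
    np.testing.assert_allclose(ab.curve.estimate, -ba.curve.estimate, atol=1e-12)


def test_difference_rejects_empty_arm():
    with pytest.raises(ValueError):
        pbr_difference([], [ms(5, True, False, 5, True)], n_boot=150, seed=1)


# ---------------------------------------------------------------------------
def test_trial_summary_orr_vs_bor():
    subjects = [ms(10, True, True, 30, True), ms(20, True, False, 20, True)]
    s = trial_summary(subjects, orr_timepoint=20.0)
    assert s.bor == 0.5 and s.orr == 0.5

    # the responder has lost response by day 35: counts for BOR, not ORR
    late = trial_summary(subjects, orr_timepoint=35.0)
    assert late.bor == 0.5 and late.orr == 0.0
    assert late.ttfr_median.median == 10.0


def test_trial_summary_without_responders():
    subjects = [ms(5, True, False, 5, True), ms(60, False, False, 60, False)]
    s = trial_summary(subjects)
    assert s.bor == 0.0 and s.n_responders == 0
    assert s.dor_curve is None
    assert s.ttfr_median.median is None


def test_trial_summary_dor_on_responders_only():
    subjects = [
        ms(10, True, True, 110, True),   # duration 100, event
        ms(30, True, True, 80, False),   # duration 50, censored
        ms(15, True, False, 15, True),
    ]
    s = trial_summary(subjects)
    assert s.n_responders == 2
    np.testing.assert_allclose(s.dor_curve.times, [100.0])
    np.testing.assert_allclose(s.dor_curve.estimate, [0.0])
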