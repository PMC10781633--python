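# Methods

## The three-state response model

A randomized patient starts at time 0 (randomization) in state 0, *not in
response*. A first documented overall response moves the patient to state 1,
*in response*. State 2 is absorbing and is entered on any of: death, start of
a new systemic therapy, relapse of the underlying malignancy, disease
progression (which ends a response and therefore only applies to
responders), or — for patients who never responded — the response-window
rule: once the window (week 24 = day 168 by default) has passed without a
response, the patient can no longer be scored as a responder and is treated
as having entered state 2 at the window. Transitions are progressive only:
0→1, 0→2, 1→2. A relapsing–remitting extension (1→0 transitions) is out of
scope.

The probability of being in response, PBR(t) = P(state 1 at t), is estimated
for all randomized patients as the difference of two product-limit curves,

    PBR(t) = ĝ(t) − ĥ(t),

with ĥ the Kaplan–Meier survival curve of U (time of leaving state 0 —
first response, direct absorption, or the window) and ĝ that of V (time of
entering state 2). Both variables are subject to right censoring (loss to
follow-up, analysis cutoff); a patient censored while response-naive is
censored in both variables at the same time, a patient censored while in
response is an event for U and censored for V. With no censoring the
estimator reduces exactly to the empirical fraction of patients in state 1.

## Event-derivation rules

Raw records carry an optional first-response time, an optional first
terminal event with a reason code, and a last-follow-up time. Derivation
applies, in order: (a) a response at or before the window ⇒ state 1 at that
time (a recorded response *after* the window is a validation error — silent
truncation would hide data errors; callers must pre-truncate deliberately);
(b) responders absorb at their terminal-event time or are censored in
state 1 at last follow-up; (c) never-responders with a terminal event
(death / new therapy / relapse — progression is not an absorbing trigger for
them) at or before the window absorb at that time; a terminal event exactly
at the window is taken as the informative trigger rather than the window
rule; (d) never-responders followed to the window without such an event
absorb at the window; (e) never-responders lost earlier are censored in
state 0. An optional administrative analysis cutoff censors all later
information first. Response and terminal event on the same day put the
patient through state 1 with zero duration (the latent ordering U ≤ V, with
equality allowed).

The window default is day 168 (24 × 7). A 28-day-cycle reading of "week 24"
(Cycle 7 Day 1) would give day 169; the window is a configuration value so
either convention is reproducible. Times are days since randomization, as
floats; ties are allowed.

## Product-limit conventions

Ties between events and censorings at one time are resolved events-first
(the censored subject remains at risk for that time's events). Pointwise CIs
for survival probabilities use the complementary log-log transform with
Greenwood variance, truncated to [0, 1]; where S = 0 the variance is set
to 0. Median CIs are Brookmeyer–Crowley (the times whose pointwise log-log
interval contains 0.5). These transforms are the common defaults of survival
software; the package makes no claim that any particular published table
used the same ones. Failure-free survival takes relapse, new systemic
therapy and death as events (not progression), censoring at last follow-up.

## Uncertainty for PBR curves

No variance formula is committed for ĝ − ĥ; pointwise intervals come from a
nonparametric bootstrap resampling subjects with replacement (arms
independently for difference curves), evaluating each replicate on the
original jump grid, and taking percentile bands. Defaults: `n_boot = 2000`
(minimum 100 enforced — percentile tails are unstable below that), an
explicit integer seed is required, and bands are widened, if necessary, to
contain the point estimate so the band invariant lower ≤ estimate ≤ upper
holds even at extreme quantile interpolation. Measured calibration at the
package's reference rates (n = 200 per arm, 500 simulated trials, the
acceptance suite): 95.0% empirical coverage of the closed-form difference at
t = 50 for the nominal 95% interval.

Negative values of ĝ − ĥ can occur under uneven censoring; occupation
probabilities are nonnegative, so the estimate is clipped at 0 with a logged
warning while the raw difference is retained on the result object.

## EDoR

The expected duration of response restricted to [0, τ] is the exact area of
the PBR step function (rectangle sums, no quadrature). On uncensored data it
equals the sample mean of per-patient time in state 1 truncated at τ. In the
exponential model without the window rule the closed form is
(λ01/(λ01+λ02))·(1/λ12); with the window it is ∫₀ᶜ p1 + p1(c)/λ12.

## The exponential Markov oracle and simulator

With constant intensities λ01, λ02 (out of state 0) and λ12 (loss of
response), the occupation probabilities are closed-form: for t ≤ c,
p0 = e^{−(λ01+λ02)t} and p1 = λ01(e^{−λ12 t} − e^{−(λ01+λ02)t})/((λ01+λ02)−λ12),
with the limit λ01·t·e^{−λ12 t} when the denominator vanishes (implemented
via `expm1`, so the near-degenerate regime is computed stably; the
acceptance suite verifies that the general branch converges linearly to the
degenerate branch with a Richardson-extrapolated limit accurate to 1e−8).
Past the window, p0 drops to 0 (its remaining mass absorbs at c) and state 1
drains exponentially: p1(t) = p1(c)·e^{−λ12(t−c)}. The closed form was
cross-checked against numerical integration of the forward Kolmogorov
equations before being frozen into the tests.

The simulator draws, per subject, competing exponential times out of
state 0, then a loss-of-response time for responders, applies the window
rule and censoring, and emits both the multistate record and a realistic
raw-timeline view (terminal reasons drawn uniformly from the categories
applicable to the transition; a never-responder's terminal event occurring
after the window is recorded in the raw view but still derives to window
absorption). Randomness uses one root seed with per-subject
`SeedSequence(seed, spawn_key=(arm, subject))` substreams, so enlarging an
arm never reshuffles earlier subjects.

Censoring is independent of the response process: `none`, `administrative`
(fixed time) or `exponential` (constant dropout hazard). A follow-up horizon
(default 3650 days) acts as an administrative analysis cutoff in every mode
so all records stay finite; at the rate scales used it is far beyond the
timescale of interest and censors essentially nothing when `kind="none"`.

### Default trial conditions

`default_two_arm_config` emulates a steroid-refractory cGvHD trial of the
shape used throughout the tests and the acceptance script: 165 vs 164
patients, window 168 days, mild exponential dropout (5×10⁻⁴/day) and a
3-year analysis horizon. Rates (per day):

| arm     | λ01    | λ02    | λ12    | implied BOR | implied TTFR median | implied PBR(365) |
|---------|--------|--------|--------|-------------|---------------------|------------------|
| active  | 0.024  | 0.007  | 0.0010 | ≈ 0.77      | ≈ 29 d              | ≈ 0.55           |
| control | 0.0139 | 0.0085 | 0.0025 | ≈ 0.61      | ≈ 50 d              | ≈ 0.27           |

These were chosen once, from the closed forms, to produce response rates,
response timing and response durability typical of an effective JAK-inhibitor
arm versus best-available therapy in this disease; they are the package's
fixed reference conditions, not tuning knobs.

What the simulator does *not* emulate: visit-grid interval censoring
(responses are observed in continuous time, whereas real trials assess every
few weeks), non-Markov waiting times, covariate-dependent hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the estimator under the stated model, not robustness to those features of
real data.

## Problem sizes used in the test suite

Exactness checks run on hundreds of small random cohorts (n ≤ 50);
large-sample recovery uses one arm of n = 5000 (sup-norm distance to the
closed form below 0.03 over the first year, 0.05 under administrative
censoring at day 400); EDoR unbiasedness uses n = 20 000 latent durations;
difference-CI calibration uses 500 trials of n = 200 per arm with 500
bootstrap replicates, evaluated at t = 50. These sizes make every
Monte-Carlo tolerance a small multiple of the corresponding standard error
while keeping the default `pytest` run around one to two minutes.

## Known limitations

* The estimator targets the progressive model; data with regained responses
  (1→0) must be re-coded (e.g. first response only) before use.
* Percentile-bootstrap bands are pointwise, not simultaneous; no global test
  of curve equality is provided.
* ĝ − ĥ is not guaranteed monotone or nonnegative in small samples; clipping
  introduces a (conservative) boundary bias exactly at 0.
* Greenwood-based CIs and the Brookmeyer–Crowley median interval are
  asymptotic; with a handful of subjects they are decorative at best.
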