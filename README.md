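# pbrkit

Nonparametric estimation of the **probability of being in response** (PBR,
also known as PBIR) for randomized clinical trials whose efficacy is judged
by response to treatment — for example trials in chronic graft-versus-host
disease (cGvHD), where overall response per the NIH 2014 consensus criteria
is the standard endpoint.

## The problem and the estimator

Response-based endpoints are usually reported as a response *rate* at a fixed
visit (ORR), a best-overall-response rate over a window (BOR), and a duration
of response (DOR) computed on responders only. None of these shows, on one
curve and using *all* randomized patients, how response builds up and decays
over time. The PBR function does: under a progressive three-state model

```
state 0 (not in response) ──λ01──▶ state 1 (in response)
        │                                   │
        λ02 ──────────▶ state 2 (absorbing) ◀────────── λ12
```

PBR(t) is the probability that a randomized patient occupies state 1 at time
*t* since randomization. It aggregates two right-censored time-to-event
variables — time to first response *U* and time to entering the absorbing
state *V* — through two Kaplan–Meier product-limit curves:

```
PBR(t) = ĝ(t) − ĥ(t),   ĥ = KM survival of U,   ĝ = KM survival of V
```

With complete follow-up this is exactly the empirical fraction of patients in
response at *t*. The absorbing state is entered on death, start of a new
systemic therapy, relapse of the underlying malignancy, disease progression
(responders only), or — for never-responders — at the response window
(week 24 = day 168 by default): a patient who has not responded by then can
no longer be counted as a responder, although the curves themselves are *not*
cut at the window. The area under the PBR curve up to a horizon τ is the
expected duration of response, EDoR(τ), in days.

`pbrkit` provides:

* the event rules mapping raw patient timelines onto the three-state model
  (`pbrkit.events`),
* product-limit machinery with Greenwood variance, log-log CIs and
  Brookmeyer–Crowley median intervals (`pbrkit.survival`),
* the PBR estimator, pointwise percentile-bootstrap confidence bands,
  between-arm difference curves, EDoR, the naive cumulative-responder curve
  and ORR/BOR/TTFR/DOR summaries (`pbrkit.pbr`),
* a closed-form exponential Markov oracle and a reproducible synthetic-trial
  simulator (`pbrkit.markov`),
* a statsmodels-style `PBRModel` / `PBRResults` interface (`pbrkit.model`)
  and a `pbrkit` command-line tool.

## Worked example

Simulate the package's default two-arm trial (165 vs 164 patients, rates
chosen to emulate a steroid-refractory cGvHD study) and fit the model:

```python
from pbrkit import PBRModel, default_two_arm_config

model = PBRModel.from_simulation(default_two_arm_config(seed=20))
res = model.fit(n_boot=1000, seed=21)
print(res.summary())
```

```
Probability-of-being-in-response summary
================================================================
                                       active            control
----------------------------------------------------------------
N randomized                              165                164
Responders (BOR), n (%)            120 (72.7)         100 (61.0)
In response at day 168 (%)               65.5               48.2
TTFR median, d (95% CI)     27.1 (19.0, 36.6)  46.7 (28.9, 60.2)
PBR at day 91 (%)           64.5 (57.1, 71.9)  45.4 (37.5, 53.1)
PBR at day 182 (%)          65.3 (57.9, 72.8)  47.3 (39.3, 55.5)
PBR at day 365 (%)          56.9 (48.7, 64.7)  30.9 (24.0, 38.3)
EDoR on [0, 365] (days)                 216.5              145.3
```

Reading the table: 72.7% of active-arm patients ever responded within the
window (BOR), but only 65.5% were *in* response at day 168 — the PBR row is
always below BOR because responses arrive at different times and some are
lost again. The active arm responds earlier (median 27 vs 47 days), stays in
response more (56.9% vs 30.9% at one year) and accumulates 71 more expected
days in response over the first year. A formal pointwise comparison:

```python
band = res.difference("active", "control", n_boot=1000, seed=22)
```

gives, at day 182, a PBR difference of +0.180 (95% CI +0.070 to +0.291) —
the interval excludes zero, so the active arm's higher response probability
at six months is not explained by sampling noise. `res.plot()` draws the
per-arm curves with the dashed cumulative-responder comparison, and
`res.plot_difference(...)` the difference with its band.

The same pipeline runs from the shell on any raw-timeline CSV
(`subject_id, arm, t_first_response, t_event, event_reason, t_last_followup`):

```sh
pbrkit simulate -o trial.csv --seed 11 --n-per-arm 100
pbrkit pbr  -i trial.csv -o out/  --n-boot 1000 --seed 3
pbrkit diff -i trial.csv -o out/  --treatment active --reference control --seed 4
```

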