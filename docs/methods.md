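# Methods

## Model structure

The cohort starts at age 65 in `INITIAL_TREATMENT` and is propagated through
monthly cycles over a 20-year horizon (H = 240 cycles; the trace has H+1
rows). The transition into cycle 1 resolves the one-time PSA-control split:
90% to `PSA_CONTROLLED`, 10% to `PSA_FAILURE`. `PSA_FAILURE` is a one-cycle
tunnel so that one-time salvage events can be attached to entry flows: after
RARP, salvage radiotherapy returns `salvage_success` (0.50) of entrants to
control and sends the rest to `ADT`; after IMRT all entrants move to `ADT`.
`ADT` and `DEAD` are otherwise absorbing; an optional monthly late-failure
hazard from `PSA_CONTROLLED` (default 0) is exposed for exploration but the
default model has only the one-time split.

Death competes proportionally with clinical transitions: every clinical
probability in a cycle is scaled by (1 − q_m), where
q_m = 1 − (1 − q_x)^(1/12) is the monthly death probability implied by the
annual life-table q_x at the cohort's current whole-year age (age advances
every 12 cycles; q_m is constant within a year of age).

## Rewards and discounting

Rewards accrue for cycles 0..H−1 on the state occupancy at cycle start; the
final row is the end state and accrues nothing. With this convention a 1-year
undiscounted horizon at constant utility 0.90 yields exactly 0.90 QALYs.
Discounting uses d(t) = 1.02^(−t/12), d(0) = 1. No half-cycle correction is
applied by default (a trapezoid-style switch exists in the settings); the
structural identity "IMRT-38 minus IMRT-20 equals exactly the upfront cost
difference" relies on the undiscounted cycle-0 lump sum.

Utilities: dead = 0; alive states get base utility 0.90 minus (additively,
floored at 0) the 0.17 PSA-failure decrement in the failure tunnel and on ADT
— applied in both, since the evidence does not separate them — and
prevalence-weighted adverse-event decrements in *all* alive states (the model
has no explicit AE substates; prevalence weighting is the expected-value
reading of "decrements were applied"). A multiplicative-combination switch is
available but off by default.

Adverse-event prevalence schedules: IMRT arms hold their reported values
(urinary 3.1%, sexual 38.9%, GI 9.8%) from month 1. For RARP the reported
one-year prevalences (urinary 9.8%, sexual 54.0%) are combined with the
one-year recovery fractions (64.5% urinary, 89.0% sexual), read as the share
of the initially affected complement recovering within the first year, giving
a month-1 prevalence p1 = p12 + cure·(1 − p12) that declines linearly to p12
at month 12. Both arms then hold the one-year value for the remaining
horizon; GI symptoms stop contributing after month 36 (their 3-year reporting
window). All durations are configurable because no source specifies them.
Two consequences of the persistence default are worth flagging: the modelled
RARP toxicity burden is front-loaded *and* long-lived, which (i) makes
IMRT-20 dominant at base case rather than marginally more expensive, and
(ii) keeps the incremental net benefit of IMRT-20 positive even when the
sexual-disutility weight is set to 0 — the weight sweep therefore has no
sign change under defaults. Shorter AE durations would reverse (ii); we do
not hard-code any because the evidence base reports prevalences at fixed
follow-up times, not durations.

Costs: cycle 0 carries the full upfront treatment cost (IMRT-20 1 076 180;
IMRT-38 1 445 580; RARP 952 880 + 260 880 + 100 000 = 1 313 760 JPY). Every
cycle accrues ADT occupancy × 224 690/12 JPY, and (RARP only) salvage
radiotherapy at 1 265 110 JPY per new failure-tunnel entrant. Per-event AE
management costs default to 0 (no tariff is tabulated) and are configurable.
Follow-up/PSA monitoring is assumed equal across arms and excluded; capital
expenditure is out of scope. Money is carried at full float precision and
rounded only in reports; USD values use 152 JPY/USD.

## Synthetic mortality

Annual death probabilities follow a Gompertz–Makeham law,
q(age) = 1 − exp(−(a + b·e^(c·age))), with hazard floor a = 5·10⁻⁴ and
log-slope c = 0.10/year — standard adult-mortality shape parameters — and b
calibrated by root-finding (Brent, on log-scale, integrating to age 130) so
that the discrete life expectancy at 65 (curtate + ½) equals 19.4 years,
typical of contemporary Japanese men. The table spans ages 65–110 and is
strictly increasing by construction. This synthetic schedule reproduces the
*level* of survivorship but not the exact age profile of any national life
table, so absolute QALY/cost totals are conditional on it; incremental
comparisons are much less sensitive because both arms share the same
mortality. A real `age,qx` CSV can be supplied anywhere a life table is
accepted.

## Sensitivity analysis

One-way analysis varies each parameter over ±25% of base (probabilities
clipped to [0,1]; decrements capped at the base utility), except PSA control
which uses the explicit 0.80–0.95 excursion applied to both arms jointly, and
reports INMB(IMRT-20 vs RARP) at each extreme. Upfront-cost parameters obey
the structural identity spread = range width, which serves as an oracle for
the loop.

The probabilistic analysis samples parameters independently — no correlation
structure is specified by the evidence — with beta marginals for
probabilities and utilities and gamma for costs, parameterized by matching
mean and sd (method of moments; log-normal is implemented for
relative-risk-type inputs but unused by default). Standard deviations are not
published, so the default is sd = 25% of the mean for every sampled
parameter, overridable per parameter; the resulting
probability-cost-effective (~0.82 at 5M JPY/QALY, 100 000 iterations) should
be read as an order-of-magnitude check, not a precise estimate. Sampled
decrements are truncated at the sampled base utility so every draw is a valid
parameter set. The desk-scale default is 10 000–100 000 iterations
(configurable up to the millions); the CEAC is evaluated on a 0–10M JPY/QALY
grid in 100 000-JPY steps and is a deterministic function of the exported
iteration records.

For speed, `run_prsa` evaluates all draws simultaneously with a vectorized
form of the cohort recursion; its numerical equivalence to sampling a
parameter set per iteration and running it through `run_cohort`/`accumulate`
is asserted in the test suite, and any sampled path or model switch outside
the vectorized support falls back to that reference route automatically.

## Validation

- **Micro-simulation oracle.** An individual-level simulation draws each
  patient's path from the same transition matrices and reward functions as
  the cohort engine (shared code path, independent expectation route). Cohort
  totals agree with the oracle mean within 3 standard errors at n = 100 000
  per arm.
- **Conservation properties.** Every generated transition matrix is
  row-stochastic to 1e−12, every trace row sums to 1 within 1e−10, and the
  death column is monotone, over randomized valid parameter sets.
- **Closed-form limits.** With zero mortality the occupancy is constant from
  cycle 2: 0.90/0.10 (IMRT) and 0.95/0.05 (RARP).
- **Affinity.** INMB is affine in the sexual-disutility weight with slope
  λ · dec_sexual · Σ_t d(t)/12 · alive(t) · Δprevalence(t), matched by finite
  differences to 1e−6 relative.

The synthetic inputs emulate the *structure* of the decision problem (state
dynamics, fee-schedule costs, trial-reported prevalences), not
patient-level heterogeneity, treatment-center variation, or the true
age-specific mortality profile — passing tests certify internal consistency
and reproducibility of the pipeline, not the clinical accuracy of any single
absolute total.

## Numerical conventions and edge cases

- Probabilities are validated into [0,1] at construction; any invalid config
  value fails fast naming the field.
- A zero-year horizon yields a single-row trace and zero totals (not even the
  upfront cost accrues, since no cycle elapses).
- ICER is reported as a ratio only when ΔQALY and ΔCost share a sign;
  otherwise the dominance label (`dominant`/`dominated`), and `undefined`
  when ΔQALY = 0. INMB is reported in all cases.
- The sweep's crossing weight is linearly interpolated at the first INMB sign
  change and reported to three decimals; when the INMB keeps one sign across
  the grid no crossing is reported.
- Exports use round-trippable float formatting; re-reading iteration records
  reproduces the CEAC bit-identically.

## Known limitations

- No prostate-cancer-specific excess mortality (reasonable for low-risk
  disease over 20 years; an optional late-failure hazard exists but no
  cancer-death rate is modelled).
- AE durations and month-1 reconstruction are modelling choices on top of
  fixed-time prevalence data; conclusions that depend on long-run AE burden
  (notably dominance at weight 0) should be stress-tested through the
  duration settings.
- Parameter uncertainty magnitudes are assumptions (25% cv), not estimates.
- Active surveillance, brachytherapy, SBRT, proton therapy and ARSI pathways
  are out of scope, as are societal costs and capital expenditure.
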