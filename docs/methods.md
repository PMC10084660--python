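# Methods

This note documents the models and procedures implemented in `rxmsm`, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-data experiments can show.

## Episode derivation (gap method)

Follow-up is the half-open interval [0, t_exit) in integer days. Dispensings
are grouped by the gap rule: a dispensing at distance ≥ `gap_days` (default
90) from the immediately preceding one opens a new medication cycle;
anything closer joins the current cycle. "Less than 3 months apart" is read
strictly, so a gap of exactly 90 days starts a new cycle — the boundary case
must be deterministic. A cycle ends at

```
end = last_rx + clip(supply_days, lower = 90, upper = next_cycle_start − last_rx − 1)
```

truncated at t_exit. The lower clamp is the rule's 3-month minimum stay
("month" = 30 days throughout the cycle rules, so 3/4/5 months = 90/120/150
days); the upper clamp keeps cycles disjoint from the following cycle. When
both bind (the next cycle starts exactly 90 days after the last dispensing,
making the upper bound 89 days), the upper bound wins — any other ordering
would produce overlapping cycles. The last cycle has no upper clamp, since
no next cycle defines one. When the gap threshold is varied (120/150 days)
the 90-day minimum stays fixed: the sensitivity analysis varies the
definition of "same cycle", not the minimum stay.

Additional conventions: same-day duplicate dispensings are merged with
supplies summed (register extracts commonly contain split packs); a
dispensing dated exactly at t_exit is dropped with a warning (half-open
follow-up); washout ineligibility means any dispensing in [−365, 0) days.
Intervals between cycles are discontinuation periods; the interval before
the first dispensing is the pre-initiation period. Every timeline exactly
partitions [0, t_exit), which the tests verify against an independent
day-resolution implementation.

## Multi-state structures

Structures A–G share states built from these episodes. A: start → cycle₁.
B: adds death as a competing event. C: adds cycle₁ → death (illness–death).
D: adds discontinuation₁ with disc₁ → death. E: one generic cycle state and
one generic discontinuation state with a back-transition (bidirectional).
F: a recurrent chain cycle₁ … cycle₆, disc₁ … disc₅, with death reachable
from every non-absorbing state; subjects entering the 6th cycle are treated
as chronic users and can only exit to death — episodes beyond the cap are
merged into the cycle₆ visit. G: the same graph as F with constraint tags.

In structure D the discontinuation₁ state means "has exited the first cycle
and is still alive", so by default a re-entry into a later cycle does **not**
end the disc₁ visit; death remains the only modelled exit. The alternative
convention (censor disc₁ → death at re-entry) is available via
`censor_disc1_at_reentry=True`. In structure C, analogously, cycle₁ means
"ever initiated and alive".

Transition data are long-format: one row per (subject, visited state,
allowed exit), with `event = 1` only for the exit actually taken. Under the
reset clock (semi-Markov, the default) each row's time is the sojourn in the
state; under the forward clock (Markov) times are measured from the start of
follow-up and the state-entry time enters as left truncation; under the mix
clock, death-bound transitions use the forward clock and all others reset.
Zero-length visits (e.g. a cycle starting on the exit day) are dropped with
a logged count. Times are expressed in years (365.25 days) for modelling.

## Transition-intensity models

Each transition uses a Royston–Parmar flexible parametric model,

```
log H(t | x) = s(ln t; γ) + x'β + case · s_td(ln t; δ)
```

with s a restricted cubic spline with `baseline_df` basis columns (default
4; boundary knots at the extreme log event times, interior knots at equally
spaced centiles — the conventional placement, configurable since the
authors' knot convention for this family is tool-dependent), covariates
x = case status, age group (<50 / 50–59 / 60–69 / 70+) and their
interactions, and a time-dependent case effect s_td with `td_df` = 3 on
transitions into a discontinuation state and on start → death. The hazard
follows analytically, h(t) = H(t)·(ds/d ln t)/t, and the log likelihood with
delayed entry is Σ d·ln h(t) − H(t) + H(t₀). With df = 1 and no
time-dependent effect the model is exactly Weibull, which the tests use as
an independent oracle (direct Weibull MLE, and lifelines as a second
cross-check); agreement is at 1e-4 relative.

Constrained joint estimation (structure G) stacks all transitions into one
likelihood with a parameter-index map: transitions in a *shared* group (all
cycle_k → death; all disc_k → death) use a single parameter vector, with
knots placed on the group's pooled event times; transitions in a
*proportional* group (cycle_k → disc_k, k = 1..5; disc_k → cycle_{k+1})
share the baseline spline and covariate effects and differ by additive
log-scale intercepts (the first member is the reference). Time-dependent
case effects are restricted to the two start-of-follow-up exits. A structure
without constraint groups reproduces the per-transition fits to 1e-6 in log
likelihood, which the tests assert.

Numerical choices: analytic gradients; BFGS followed by Newton polishing
with a finite-difference Hessian until max|score| < 1e-5 (fits failing this
are flagged unconverged); variance from the inverse numeric Hessian; the
spline slope inside the log hazard passes through a linearly extended log
below 1e-10, which pushes the optimizer away from non-monotone cumulative
hazards (the known pathology of this family), and fits with a negative
hazard at any observed event time are flagged; linear predictors are clipped
at ±300 inside the likelihood to keep line searches finite. Starting values
come from the exponential fit (log crude rate, unit slope on ln t).

Sparse transitions — the recurrent chain's high-order states lose events
quickly — degrade gracefully in the pipeline: the spline df steps down when
events are fewer than ~5 per flexibility unit, transitions with fewer than
10 events use the closed-form exponential (crude-rate) MLE, and event-free
transitions get a near-zero hazard, the limit of their likelihood. Units of
a joint fit with a single distinct event time are likewise replaced by the
crude-rate exponential; these substitutions are logged.

## Prediction by microsimulation

Given fitted intensities and a covariate pattern (default: age 60–69, each
case status), `n_sim` individuals (default 100,000) start in the requested
state and repeatedly draw competing exit times — independently per allowed
transition, minimum wins, which is valid because cause-specific hazards
fully determine the joint exit law — until death or the horizon (the last
grid time). Event times solve H(t) − H(t₀) = −ln u by vectorized bisection
on log time (interval shrunk below 1e-14; draws whose total hazard over the
horizon is insufficient are censored in state). Under the reset clock t₀ = 0
per visit; under forward/mix clocks, death-bound draws condition on the
absolute entry time. Conditional predictions (e.g. since entering the 2nd
cycle) start in that state at reset time 0; under forward clocks they
require a positive entry time s, settable in the request (the natural
default is the median observed entry time of the conditioning state).

Occupancy at each grid time is the exact proportion of simulated
individuals, so the probabilities sum to one by construction; Monte-Carlo
SEs are binomial. Length of stay is the cumulative trapezoid of occupancy;
ever-visit curves come from first-entry times. Parameter uncertainty
redraws each transition's coefficients from N(θ̂, V̂) (independently across
transitions fitted separately; a non-positive-definite V̂ is repaired by
eigenvalue flooring with a warning), re-simulates, and reports pointwise
percentile bands.

An independent Aalen–Johansen product-integral oracle covers the Markov
(forward-clock) case: P(t+h) = P(t)(I + Qh + (Qh)²/2) with Q at the
midpoint, automatic step refinement on diagonal overshoot, and row
renormalization against drift. Tests hold the microsimulation to within 3
Monte-Carlo SEs of this oracle (and of closed forms for the competing-risks
and illness–death cases), and verify that reset- and forward-clock
predictions coincide for constant hazards (memorylessness).

## Synthetic registry generator

The generator emulates the features of a register-linkage cohort that the
analysis relies on: a 1:5 case:comparator cohort with a common age-group
distribution (default 20/25/30/25% across <50/50–59/60–69/70+); a latent
alternating cycle/discontinuation process simulated by clock-reset
competing-risks draws from transition-specific Weibull hazards with
proportional case and age effects (an optional log-time-linear case
interaction gives a time-dependent case effect in closed form); death as an
absorbing state and administrative censoring at 7.5 years; and dispensings
emitted inside true cycles — one at the cycle start, then at gaps drawn
uniformly from 55–85 days (strictly below the 90-day threshold), each with
a supply drawn from {30, 60, 90, 100} days with weights 0.35/0.30/0.30/0.05.
Sojourns are rounded up to whole days so dispensing dates are integers.

Default hazards are anchored to the qualitative features reported for such
cohorts: about 10% of comparators initiate within 6 years with cases at
roughly three times the hazard in the first year (attenuating later); low
background mortality with a strong age gradient and elevated case
mortality; true cycle lengths with median ≈ 40 days, so that most first
cycles hold a single dispensing and the derived median first-cycle duration
sits exactly at the 3-month floor; and a median ≈ 2.2 years to the next
cycle, leaving roughly 40% of users with a single cycle over follow-up. The
within-cycle gap and supply distributions are defaults of this package, not
estimates from any real register.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: matching beyond the case:comparator ratio
(no county or calendar matching), comparators becoming cases mid-follow-up,
emigration as a distinct exit (collapsed into censoring), dose tapering,
drug switching, stockpiling, calendar-time effects, or frailty / unmeasured
heterogeneity. Tests on synthetic data validate the algorithms and the
estimation machinery, not the clinical realism of any particular parameter
value.

## Scales used in the shipped experiments

The test suite and the acceptance script run at desk scale: cohorts of
900–6,000 subjects, 100,000 microsimulation draws where closed forms are
compared (Monte-Carlo SE ≈ 0.0015), 200 replicates for confidence-interval
coverage at n = 500, and df = 1 (Weibull) truths for parameter-recovery
experiments so that estimates have exact independent oracles. Pipeline
smoke tests use reduced spline df and 5,000 draws; full-flexibility runs
(df = 4, td 3, 100,000 draws) are the library defaults.

## Known limitations

* Closed-form (non-simulation) prediction is not available for semi-Markov
  cyclic structures; everything beyond the Markov case goes through
  microsimulation.
* Each transition uses a single timescale; models with multiple
  simultaneous timescales per transition are out of scope.
* Joint frailty models for recurrent events with a terminal event are out
  of scope.
* The chronic-user cap (cycle₆ absorbs all later cycling except death) is a
  modelling convention inherited by structures F and G; the bidirectional
  structure E is free of it but cannot distinguish cycle orders.
* Parameter-uncertainty bands treat separately fitted transitions as
  independent; only jointly fitted (constrained) transitions share their
  sampling covariance.
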