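# Methods

## Model structure

`alarmcea` evaluates seven smoke-alarm promotion strategies for households
with a newborn child by composing three stages, all computed as expectations
over a unit household (cohort results are a reporting rescale; every decision
analytic — frontier, CEAC, EVPI — is invariant to that scale).

**Stage 1 — intervention tree.** Four branches partition households:
(i) already owning a functioning alarm, probability `p_prev`; (ii) non-owners
who accept the offer (`p_accept`) and are enabled (`π_k`); (iii) non-owners
who accept but are not enabled; (iv) non-owners who decline. Branches
(i)+(ii) enter stage 2 with a functioning alarm:
`p_start = p_prev + (1 − p_prev)·p_accept·π_k`. Delivery costs (the sum of
the strategy's component costs) fall on accepting non-owners — branches (ii)
and (iii): delivery happened even where it failed to enable. A switch
(`charge_nonacceptors`) instead charges all offered non-owners. Usual care
has `π ≡ 0` and zero delivery cost. A single `p_accept` is shared by all
strategies (there is no evidence to differentiate acceptance by programme).

**Stage 2 — pre-school Markov model, ages 0–4.** Joint states
(alarm functioning × child never-severe/post-severe) plus an absorbing dead
state. Within a yearly cycle events apply in a fixed order: fire
(`p_fire`) → injury given fire (`p_injury_func` / `p_injury_nonfunc`) →
severity from the alarm-state-specific (minor, moderate, severe, fatal)
split → background life-table mortality → alarm decay/repair
(`d_decay`/`d_repair`), which takes effect from the next cycle. At most one
fire, hence one injury, can occur per cycle by construction, and injury
hazards are history-independent. Minor/moderate injuries incur a one-off
acute cost and no utility decrement; a severe injury sets a lifelong
post-severe flag (decrement `du_severe`, ongoing annual cost
`c_severe_annual`, both accruing from the event cycle onward); a repeat
severe injury to an already post-severe child adds acute costs only; a fatal
injury books the fatality costs in the event cycle. Each fire also books
fire & rescue attendance (other public sector) and property damage
(household) costs.

**Stage 3 — lifetime Markov model, ages 5–99.** Healthy / post-severe / dead,
with life-table mortality applied equally to both living states by default
(an optional hazard ratio `severe_mortality_hr` imposes excess post-severe
mortality; nothing in the evidence base pinned it, so it defaults to 1).
Healthy accrues the age-specific utility norm `u(a)`; post-severe accrues
`u(a) − du_severe` and `c_severe_annual`. The model stops at age 99
inclusive; survivors beyond contribute nothing.

## Numerical conventions

- Yearly cycles; state-occupancy rewards valued at cycle start; **no
  half-cycle correction** (keeps results exactly reproducible and matches a
  per-household event simulation with start-of-cycle accrual).
- One discount clock from birth: a reward at age `t` is discounted by
  `(1+r)^(−t)`, `r = 0.035` on both costs and QALYs.
- A child newly severe in cycle `t` accrues the decrement and ongoing cost in
  cycle `t` itself (counted before that cycle's background mortality).
- Children fatally injured or dying in cycle `t` still receive the cycle-`t`
  start-of-cycle utility.
- Occupancy is checked to stay non-negative and sum to one (tolerance 1e-8 on
  inputs; conservation holds to machine precision by construction).
- Everything is written with numpy broadcasting: a parameter draw may carry
  scalars or length-`n_draws` vectors, so a full 5,000-draw PSA of all seven
  strategies runs in a few seconds without per-draw Python loops.

## Uncertainty propagation

Each uncertain input is declared in a parameter table as a distribution
(beta for probabilities, gamma/lognormal for costs, dirichlet for severity
splits, fixed for point values; a fixed *vector* is allowed so a probability
split can be made exactly degenerate). One seeded generator is threaded
through all sampling; the seed is recorded in the output metadata. Parameter
draw *i* is paired with effectiveness-posterior row *i* — no resampling — so
the number of model simulations equals the number of posterior draws (5,000
in the base case).

Strategy effectiveness enters as `π_k`, the probability that an accepting
non-owner ends up with a functioning alarm. The shipped posterior *emulates*
network-meta-analysis MCMC output: multivariate-normal log-odds ratios for
the six active strategies (exchangeable correlation 0.5, sd 0.3), mapped
through the inverse logit against a baseline log-odds of `logit(0.35)`. Mean
log-odds ratios (0.20, 0.50, 0.65, 0.65, 0.35, 0.85 for E, E+FE, E+FE+HI,
E+FE+F, E+HI, E+FE+F+HI) increase with the number of components, equipment
counting for more than inspection — the qualitative ordering the synthesis
literature reports. The log-odds scale is the natural output scale of such
syntheses and guarantees `π ∈ (0,1)`.

## The synthetic fixture

The source analysis printed only a few of its inputs; the full input tables
were never made available. The fixture therefore fixes the printed values
exactly —

| parameter | value |
|---|---|
| `p_prev` | 0.80 |
| `p_accept` | 0.90 |
| `d_decay`, `d_repair` | 0.1 each (the single published "decay/repair factor" is read as applying in both directions; SA3 zeroes both) |
| `p_injury_nonfunc` | 0.91 |
| `r` | 0.035 |
| `h` (children/household) | 1 |
| cohort | 100,000 |

— and supplies documented synthetic values for everything else, chosen once
for epidemiological plausibility: annual fire probability beta with mean
0.002 (of the order of UK domestic-fire counts over households);
`p_injury_func` beta mean 0.60 (< 0.91: a functioning alarm protects);
severity splits dirichlet with means (0.80, 0.15, 0.03, 0.02) functioning and
(0.70, 0.20, 0.06, 0.04) non-functioning (severe+fatal a small fraction of
injuries, worse without an alarm); component delivery costs gamma with means
£20/£30/£40/£50 for E/FE/F/HI (UK home-safety-scheme delivery scale); acute
injury costs £250 / £2,500 / £60,000 (minor/moderate/severe, the last being
a >5-day intensive-care stay) and £5,000/yr ongoing post-severe care, all
NHS/PSS; £1,500 fatality (coroner/autopsy, household), ~£608k lost
productivity per fatality; £2,500 fire & rescue attendance per fire and
~£8,800 property damage per fire; `du_severe` beta mean 0.15; utility norms
a UK-like step function from 0.94 (ages 0–24) to 0.73 (75+); and a synthetic
life table with infant mortality 4.5/1,000 and a Gompertz old-age term
reaching q≈0.5 at 99.

**What this emulates and what it does not.** The fixture reproduces the
*structure* of the published inputs (distribution families, support,
orderings, the printed point values) but not their numerical content.
Passing tests therefore demonstrate that the machinery is correct — stage
composition, discounting, dominance logic, probabilistic propagation,
scenario wiring — and that qualitative findings (rare fires make per-child
QALY differences tiny; more complex interventions buy small health gains at
steeply rising ICERs) emerge for plausible inputs. Absolute QALY/cost/EVPI
levels characterise the fixture, not the published study, and no calibration
toward the published absolute outputs is performed or intended. Real data
features not emulated: parameter correlations beyond the effectiveness
posterior, age- or season-dependent fire risk, household moves, repeat-fire
risk dependence, and sibling spill-overs.

## Household scaling and perspectives

Benefits accrue to a single child by default. With `h` children per
household (SA4: 1.8), QALYs and child-borne costs (treatment, ongoing care,
fatality and productivity costs) multiply by `h` — children are assumed to be
of similar age and to suffer the same consequences in a fire — while
household-level costs (delivery, fire & rescue, property) do not.

Perspectives select cost categories: `public_sector` (base) counts NHS/PSS +
other public; `NHS_PSS` drops fire & rescue and other non-health public
costs; `extended_household` adds household costs (property damage, fatality,
equipment) but never productivity. Intervention delivery cost is counted
under every perspective — the comparison of interest is always "pay for the
programme, who saves what".

## Decision analytics

Per-strategy means over all draws feed the incremental analysis: sort by
effectiveness (ties by ascending cost; equal-cost equal-effect duplicates
collapse onto the earlier index), remove strictly dominated strategies, then
iteratively remove extendedly dominated ones until ICERs strictly increase
along the frontier. CEACs count, per threshold, the fraction of draws in
which each strategy attains maximal net monetary benefit, ties awarded to the
cheaper strategy (deterministic and conservative toward cheaper care; a
measure-zero event for continuous draws). Per-decision EVPI is
`E[max_k NMB_k] − max_k E[NMB_k]`, clipped at zero against floating-point
negatives; population EVPI multiplies by the affected population summed over
the decision horizon, discounted from year 0 at the model's rate (an
undiscounted variant is a flag).

## Scenarios

Declarative fixed-value overrides on the parameter table, everything else —
seed, posterior, life table — shared: SA1 `p_prev=0.5`; SA2 `p_accept=0.5`;
SA3 `d_decay=d_repair=0`; SA4 `h=1.8`; SA5
`p_injury_func=p_injury_nonfunc=0.91`. SA5 by default leaves the severity
splits alarm-specific (the published SA5 still shows nonzero QALY
increments, implying a residual alarm effect); `equalise_severity=True`
additionally ties the *realised* severity splits, after which health outcomes
are provably independent of alarm coverage (a property the suite tests).

## Verification

- **Closed forms:** discounted QALY annuities and geometric survival sums to
  1e-10; tree arithmetic and branch bookkeeping exactly.
- **Independent oracles:** the frontier classifier is checked against
  exhaustive pairwise/segment enumeration on 1,000 random instances of up to
  8 strategies; EVPI against per-draw argmax recomputation; posterior means
  against a 10⁶-sample brute-force transform.
- **Microsimulation:** a 200,000-household stochastic per-household
  simulation applying the same event rules reproduces cohort-expectation
  QALYs, itemised costs and event counts within 4 Monte-Carlo standard
  errors (3 seeds × 2 strategies). Problem sizes (200,000 households, 5,000
  PSA draws) were chosen to make Monte-Carlo error small relative to the
  quantities compared while keeping the whole suite runnable in well under a
  minute of CPU.
- **Properties (seeded/derandomised hypothesis where appropriate):**
  occupancy conservation with an absorbing dead state; monotonicity of
  starting coverage in prevalence/acceptance/effectiveness and of outcomes
  in injury risk; linearity of the lifetime stage in its start distribution;
  perspective nesting (NHS/PSS ⊆ public sector ⊆ extended household);
  CEAC columns summing to one; frontier invariance under affine rescaling;
  bitwise run-to-run determinism at fixed seed.

## Known limitations

- No half-cycle correction; results are exactly reproducible but stage
  rewards are start-of-cycle approximations.
- No fires or new injuries after age 4; only pre-school injury consequences
  are carried forward.
- Acceptance is all-or-nothing per strategy; no partial component uptake.
- The fixture's absolute levels are synthetic; only structure, orderings and
  scenario contrasts are meaningful for external comparison.
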