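# alarmcea

Decision-analytic cost-effectiveness modelling of interventions that promote
**functioning smoke alarms** in households with pre-school children.

Fire-related injury is a leading cause of death and disability in young
children, and functioning smoke alarms reduce the risk of injury when a house
fire occurs. Public-sector programmes promote alarm ownership with different
mixes of components — education (E), free/low-cost equipment (FE), equipment
fitting (F) and home safety inspection (HI) — and a decision maker operating
under a fixed budget needs to know not just which mix is most *effective* but
which is most *cost-effective*. `alarmcea` implements a three-stage model to
answer that question for seven strategies (usual care, E, E+FE, E+FE+HI,
E+FE+F, E+HI, E+FE+F+HI):

1. **Intervention decision tree.** A household may (i) already own a
   functioning alarm (probability `p_prev`); otherwise it accepts the offered
   intervention with probability `p_accept` and, if it accepts, becomes an
   *enabled* functioning-alarm household with strategy-specific probability
   `π_k` drawn from the posterior of a network meta-analysis of trial
   evidence. The tree yields the starting alarm coverage
   `p_prev + (1 − p_prev)·p_accept·π_k` and the expected delivery cost.
2. **Pre-school Markov model (ages 0–4).** Yearly cycles with at most one
   house fire per cycle (probability `p_fire`); given a fire, a child injury
   with alarm-state-specific probability; given an injury, a
   (minor, moderate, severe, fatal) severity split; background mortality from
   a life table; and an annual decay/repair probability moving alarms between
   functioning and non-functioning states.
3. **Lifetime Markov model (ages 5–99).** Carries the consequences of a
   severe pre-school injury — a lifelong utility decrement `du_severe` and an
   ongoing annual care cost — through the rest of life, with life-table
   mortality and age-specific population utility norms.

Costs (GBP, itemised as NHS/PSS, other public sector, household, and
productivity, under selectable perspectives) and QALYs are discounted to
birth at 3.5 % per year. Uncertainty is propagated by probabilistic
sensitivity analysis: 5,000 Monte-Carlo draws of all parameters, paired
row-by-row with 5,000 effectiveness posterior draws. On top of the PSA matrix
the package computes the incremental cost-effectiveness frontier (with
dominance and extended dominance), ICERs, net monetary benefit
(`λ·QALYs − costs`), cost-effectiveness acceptability curves, and the
expected value of perfect information (per decision and for a population),
plus the standard one-way scenario analyses (SA1–SA5) and perspective
variants.

Because the original study's full input tables were never published, the
package ships a documented **synthetic fixture**: the handful of printed
values are fixed exactly (prevalence 0.80, acceptance 0.90, decay/repair 0.1,
injury probability without a functioning alarm 0.91, discount rate 3.5 %, one
child per household, cohort 100,000) and all remaining inputs are plausible
synthetic defaults — see `docs/methods.md` for what that does and does not
allow you to conclude.

## Worked example

```python
import alarmcea as ac
from alarmcea.cea import population_evpi

run = ac.run_scenario("base")          # 5,000 draws, synthetic fixture
print(run.summary())
pop = population_evpi(run.evpi.per_decision, 31000, 10, 0.035)
print(f"population EVPI: GBP {pop:,.0f}")
```

prints (per household; multiply by the 100,000-household cohort for
population totals):

```
scenario: base (base case)
perspective: public_sector, n_draws: 5000, seed: 20140516
 strategy  expected_qalys  expected_cost  incremental_qalys  incremental_cost        icer               status  prob_ce_30000  prob_ce_50000
       UC          24.968         79.192                NaN               NaN         NaN             frontier          0.125          0.092
        E          24.969         79.435              0.000             0.242     725.908             frontier          0.694          0.591
     E+FE          24.969         84.225              0.000             4.791  79,254.537             frontier          0.142          0.214
  E+FE+HI          24.969         92.891                NaN               NaN         NaN extendedly_dominated          0.008          0.026
   E+FE+F          24.969         91.116                NaN               NaN         NaN extendedly_dominated          0.017          0.044
     E+HI          24.969         88.110                NaN               NaN         NaN            dominated          0.011          0.020
E+FE+F+HI          24.969         99.686              0.000            15.460 222,033.451             frontier          0.003          0.013
per-decision EVPI at GBP 30,000/QALY: GBP 0.98 per household
population EVPI: GBP 260,587
```

Reading this: every strategy delivers ≈ 24.97 discounted QALYs per child —
house fires are rare, so QALY differences between strategies are of order
10⁻⁴ and appear as 0.000 at three decimals, while expected public-sector
costs range from £79 to £100 per household. Three strategies are excluded by
dominance or extended dominance; along the remaining frontier each step's
ICER (incremental cost per QALY gained) rises steeply, and at a £30,000/QALY
threshold education alone is the most likely to be cost-effective (0.69).
The per-decision EVPI of £0.98 per household says resolving *all* parameter
uncertainty before deciding is worth about £1 per household, or ≈ £261,000
for ten annual cohorts of 31,000 households. With the synthetic fixture these
absolute numbers characterise the fixture, not the published study.

The same analysis from the shell:

```bash
alarmcea fixture --out fixture/                    # write the input CSVs
alarmcea run --scenario base --out results/ \
    --params fixture/parameters.csv --lifetable fixture/life_table.csv \
    --norms fixture/utility_norms.csv --posterior fixture/posterior.csv
alarmcea run --scenario SA4 --out results-sa4/     # built-in fixture
```

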