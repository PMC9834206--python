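# teammrt

Tools for designing and analyzing **cluster micro-randomized trials (MRTs) of
gamified team competition** in mobile-health studies — the setting where
teams of medical interns are re-randomized every week to compete (or not)
against another team on wearable-measured step count or sleep minutes, and
the question is the short-term (proximal) causal effect of being assigned a
competition week.

The package provides, end to end:

- a **synthetic cohort generator** — interns nested in residency programs
  (institution × specialty), daily step/sleep/mood streams with realistic
  baselines (steps ≈ 8121 ± 3229/day, sleep ≈ 420.6 ± 107.5 min/day),
  configurable causal excursion effects, MAR missingness and dropout;
- the **weekly three-factor randomization engine**: a fair coin into the
  competition arm per team, one opponent-pairing rule per week (total /
  intra-institution / intra-specialty, each with probability 1/3), greedy
  pairing under the rule with the odd/unpairable leftover returned to the
  non-competition arm, and a fair coin for the competition type per pair;
- **team-week aggregation** (the team is the unit of analysis),
  **chained-equation multiple imputation with predictive mean matching**
  pooled by Rubin's rules, and **two-step post-stratification raking**
  (w = w1 · w2);
- the **weighted-and-centered least squares (WCLS)** estimator of causal
  excursion effects with cluster-robust sandwich variance, including
  time-varying (week) and pairing-rule moderation, linear probability models
  for participation rates, and spline (penalized/REML or natural-cubic)
  sensitivity analysis of the week-varying effect.

## The model

For team *i* in week *t* (coded 0…11), with binary competition assignment
`A_it` (P(A) = p = 1/2 by design) and team-week outcome `Y_it` (e.g. mean
daily steps), WCLS solves a weighted least-squares problem with regressors

```
Y_it ~ alpha' Z_it  +  beta0 (A_it - p~)  +  beta1 (A_it - p~) * t
```

where `Z_it` are control variables (% female, team baseline means, previous
week's outcome, week), `p~` is a centering probability (the nominal 1/2
here, so all weights are 1 and the fit is OLS with a centered treatment),
and variance is the sandwich clustered by team. Centering makes `beta`
consistent for the causal excursion effect even when the control part is
misspecified; `beta0` is the week-0 effect and `beta0 + beta1*t` the effect
after *t* additional weeks. Imputed datasets are combined with Rubin's rules
(total variance `W + (1 + 1/M) B`).

## Worked example

```python
import teammrt as tm

# moderated effect of step competition by study week, from the fitted
# time-varying coefficients (week-0 effect 185.3 steps/day, slope -14.5)
for w in (1, 6, 12):
    print(w, tm.effect_at_week(185.3, -14.5, w))
# 1 185.3
# 6 112.8
# 12 25.8

# a participation-rate effect of +0.9 percentage points over a 7-day week
# in a 1779-intern cohort is
tm.person_days_gain(1779, 0.009, 7)
# 112  extra person-days of sleep records

# enrollment flow percentages along an exclusion chain
tm.study_flow([4791, 2286, 1936, 1779])
# [100.0, 47.7, 84.7, 91.9]
```

A full synthetic trial, end to end:

```python
import teammrt as tm
from teammrt.impute import ImputationSpec

cfg = tm.RunConfig(sim=tm.SimConfig(n_teams=60, n_institutions=30),
                   imputation=ImputationSpec(m=10, n_sweeps=5),
                   master_seed=20_260_916)
bundle = tm.run_trial(cfg)
print(bundle["estimates"].query("term == 'competition'")
      [["outcome", "model", "weighting", "estimate", "se", "p"]])
```

which prints (steps rows; the generating week-0 effect is 185.3 steps/day
with slope −14.5, so the marginal effect is 105.6):

```
 outcome          model  weighting  estimate     se     p
   steps       marginal unweighted    29.372 42.049 0.487
   steps week_moderated unweighted    95.834 67.434 0.155
```

The week-0 estimate is attenuated relative to 185.3 because the imputation
model — faithful to the analysis it emulates — does not use the treatment
assignment as a predictor, so imputed days dilute the contrast (see
`docs/methods.md`). Monte-Carlo operating characteristics without
missingness (`analysis/06_operating_characteristics.py`, 200 replicates of a
150-team trial) show bias within Monte-Carlo error, 95% CI coverage of
0.945–0.960 and type-I error of 0.045–0.055.

## Analysis scripts

`analysis/01…06` are narrative drivers that regenerate every table under
`results/`: trial simulation, randomization design diagnostics, effect
fits, the worked arithmetic above, sensitivity analyses (spline effect
curves, dropout/weekly complete-case filters, MI vs complete case), and the
estimator's operating characteristics. A `teammrt` CLI with subcommands
(`simulate`, `randomize`, `impute`, `weights`, `aggregate`, `fit`,
`sensitivity`, `run`, `replicate`) wraps the same functions for shell use.

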