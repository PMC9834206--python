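# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `teammrt`, and what the synthetic-data experiments do and do not
establish.

## Design being modeled

A 12-week cluster micro-randomized trial: interns are grouped into teams
(programs with ≥ 5 interns become program-based teams; leftover interns in an
institution are pooled into one institution-based team if ≥ 5; the rest are
ineligible). Every Monday each team independently enters the competition arm
with probability 1/2; one opponent-pairing rule for the week is drawn
uniformly from {total, intra-institution, intra-specialty}; competition-arm
teams are paired greedily in a uniformly shuffled order under the rule's
constraint; the odd leftover — and any team with no rule-compatible partner —
is returned to the non-competition arm and flagged; each realized pair flips
a fair coin between a step-count and a sleep-minutes competition.

Two design details are not determined by the text of the protocol this
emulates and are config-exposed: whether the pairing rule is drawn once per
week (default) or per pair (`per_pair_rule=True`), and how unpairable teams
are treated (identically to the odd leftover, by decision). The uniform
shuffle makes leftover selection exchangeable across teams. Because of the
leftover rule, the realized probability of being in a competition is
strictly below the nominal 1/2 (≈ 0.37–0.41 for a 20-team roster under the
constrained rules; `analysis/02`); `realized_treatment_probability` measures
it by Monte Carlo, and the estimator accepts non-nominal `p` if one wants to
analyze the realized design rather than the nominal one.

## Synthetic cohort

Per intern *i*, day *d* in week *w*, each outcome is

```
y_id = b_i + trend * w + u_team + v_i + A_w (beta0 + beta1 w + offsets) + e_id
```

with `b_i` the pre-internship baseline, Gaussian team and intern random
effects, AR(1) day noise (rho = 0.3 so the imputer's 3-day lags have signal),
and `A_w` the indicator of a competition *of the matching type* that week
(any competition, for mood). Mood is a latent Gaussian clipped to [1, 10].

Defaults are the study conditions: 191 teams (~1779 interns, shifted-Poisson
team sizes with minimum 5 and mean 9.3), 90 institutions, 12 specialties with
the published cohort's marginal shares, baselines 8121 ± 3229 steps/day and
420.6 ± 107.5 sleep min/day, secular step trend −15.8/week, week-0 effects
185.3 steps and 9.8 min with slopes −14.5 and −1.9, participation uplifts
0.003 (steps) and 0.009 (sleep), and daily missingness bases 0.30/0.50/0.40
for steps/sleep/mood so that total missingness (with dropout) exceeds 30%
and 50% for steps and sleep.

Numerical choices worth flagging:

- **Step day-noise is heteroscedastic** (SD = 0.30 × the intern's underlying
  mean) and the baseline draw is floored at 500 steps/day. A homoscedastic
  Gaussian with the between-intern SD above would put ~2% of days below
  zero; clipping those at zero attenuates any additive treatment effect and
  is also unrealistic (low-volume walkers have low day-to-day variance).
- **Missingness is MAR by construction**: the day-*d* blanking probability
  is `base + coef * z - uplift * A_w`, where `z` is the standardized
  previous-day value *when that day was observed* and the standardized
  baseline otherwise, so the mechanism never reads unobserved data. Dropout
  is monotone with hazard `h0 + slope * w`, rising over the study.
- The complete (pre-missingness) records are returned alongside the masked
  copy so imputation error is directly measurable.

What the generator does **not** emulate: heavy-tailed or zero-inflated step
distributions, weekday/weekend periodicity, device-specific measurement
error, within-team outcome correlation calibrated to data (the team
random-effect SD is a free knob), and any dependence of behavior on
competition *results* (win/loss feedback). Passing tests therefore show the
pipeline's statistical properties under a Gaussian, additive-effect world,
not robustness to those features of real wearable data.

## Aggregation

The team-week summary is the mean of per-member weekly means over members
with ≥ 1 observed day (each intern contributes equally); a pooled person-day
mean is available (`method="pooled"`) and the two coincide after imputation.
Participation rate = observed person-days / (7 × all randomized members), so
dropouts count as non-participating. Previous-week outcome controls use the
team's pre-internship baseline mean at week 0 (flagged) rather than dropping
the first week.

## WCLS estimation

The estimator regresses the team-week outcome on controls plus a centered
treatment `A − p~` and its products with moderators, with per-row weights
`p~/p` (treated) and `(1−p~)/(1−p)` (untreated), solved by QR on the
sqrt-weighted design, and a cluster-robust sandwich with the team as the
independence cluster. With the nominal constant `p = p~ = 1/2` all weights
are one and the fit is exactly centered OLS (a tested identity against an
independent implementation, and HC0 equality when each cluster has one row).
No small-sample sandwich correction is applied by default; Mancl–DeRouen is
available via `ModelSpec(mancl_derouen=True)`. CIs use ±1.96·SE for single
fits and a t quantile with Rubin df for MI-pooled fits.

For the step (sleep) outcome the treatment indicator is "in a competition of
the matching type"; mood and participation use "in any competition". The
marginal type-specific treatment probability is ≈ 1/4, not the nominal 1/2
used for centering; because assignment is independent of history and of all
controls, constant-weight WCLS with any constant `(p, p~)` remains
consistent for these effects (also verified in tests), and the nominal
design is the default analysis. Participation-rate models run on the
observed (non-imputed) table — participation *is* the missingness process —
as linear probability models with the same machinery, without a
previous-week control (participation has no pre-study counterpart).

Rank deficiency raises an error naming the collinear terms (pivoted-QR
identification). A trial whose 12 weekly rule draws never select, say, the
intra-institution rule cannot identify that moderation term; the error
surfaces this rather than silently dropping it.

## Multiple imputation

Chained equations over steps → sleep → mood, M = 20 datasets (default) and
10 sweeps; each update is predictive mean matching with k = 5 donors (type-1
matching: observed predictions under the posterior mean, missing predictions
under a Bayesian parameter draw; a bootstrap draw is available). Predictors:
lags 1–3 and previous-week means of all three outcomes, sex, PHQ-9,
neuroticism, early family environment, baseline steps/sleep, and institution
and specialty as grouped mean-encoded predictors (full one-hot encoding of
~90 institutions would destabilize the regressions). Lags crossing the study
start fall back to the intern's baseline (cohort mean of observed mood for
the mood stream, which has no baseline measure). A tiny ridge (1e-8) guards
the normal equations; donor search is a sorted window with exact k-nearest
selection. PMM guarantees imputations stay within the observed support.

Like the analysis it emulates, the imputation model does **not** include the
treatment assignment or week among its predictors, so imputed person-days
dilute the treated/untreated contrast roughly in proportion to the missing
fraction; the demo fit in the README shows this attenuation, and the
MI-vs-complete-case experiment should be read as "MI removes selection bias",
not "MI is unbiased".

The MI-vs-complete-case experiment uses missingness strongly dependent on
the lagged outcome with a large (0.15) participation uplift. With an
additive, history-independent treatment effect, lagged-outcome selection
inflates both arms equally and cancels in the effect estimate; only
treatment-dependent selection intensity biases the effect, and at the
study's own uplift (0.003–0.009) that bias is far below Monte-Carlo
resolution at desk scale. The chosen configuration makes the bias mechanism
visible (complete-case estimates off by ~100–300 steps; MI tracks the
full-data fit) in a 40-team, 3-replicate experiment.

## Raking weights

`rake` is plain iterative proportional fitting on category margins
(normalized to shares), converging when every targeted weighted margin is
within `tol` (default 1e-6) of its target; weights are normalized to mean 1
(the recorded convention). The two-step scheme rakes on specialty (w1), then
on sex and race within each specialty group — surgical = {surgery, ob/gyn} —
starting from the w1-weighted sample (w2); final weight w1·w2. Finer race
categories collapse onto {White, Asian, URM-or-other} by a documented map.
Optional 1st/99th-percentile trimming is off by default. Whether weights
enter the outcome analysis is left to the analyst: the pipeline fits and
reports both weighted and unweighted models, with team-level analysis weight
= mean of member weights. `SYNTHETIC_REFERENCE_MARGINS` is a synthetic
stand-in for a national reference population (no registry data ships with
the package); by default the pipeline self-rakes (unit weights).

## Spline sensitivity

The week-varying effect `(A − p~) f(week)` can be fit with
(1) a natural cubic basis of dimension df (df = 2 is exactly the linear
model — a tested identity), or (2) a cubic smoothing spline
(`|w − k_j|^3` radial basis on 6 knots, curvature penalty
`Omega_jk = |k_j − k_k|^3`, intercept and linear trend unpenalized) with the
smoothing parameter chosen by REML — a one-variance-component mixed-model
profile likelihood optimized over log-lambda with Woodbury identities, so
the search is cheap. Pointwise CIs come from a cluster sandwich with the
penalized bread and Mancl–DeRouen bias-corrected cluster residuals, which
counteracts small-sample undercoverage of the band.

Calibration claim (and its limit): at the 150-team scale, the pointwise 95%
band covers a truly linear generating effect at each week in ~94–98% of
replicates. No claim is made about *simultaneous* coverage across all 12
weeks: for an effectively 2-df fit the joint probability that twelve
calibrated pointwise intervals cover at once has a ceiling near 0.87
(endpoint errors are negatively correlated), so whole-curve statements need
a genuine simultaneous band, which this package does not provide.

Complete-case variants: `complete_case_dropout` blanks imputed values after
an intern's last observed day; `complete_case_weekly` removes team-weeks
with more than `max_missing_per_week` missing person-days of the outcome
(default 5, the unit read as person-days per team-week; at ~30% daily
missingness with 9-member teams this literal rule removes nearly all
team-weeks, so the threshold is config-exposed and `analysis/05` reports a
quartile-scaled alternative alongside it). Both filters are idempotent.

## Simulation-study harness and problem sizes

`replicate_study` repeats simulate → randomize → aggregate → fit (no
missingness; the harness characterizes the estimator) and reports bias,
RMSE, CI coverage and rejection rates with Monte-Carlo SEs. The package's
own experiments use: 500 replicates of a 150-team trial for
coverage/type-I (the acceptance suite), 200 replicates for the analysis
driver, 40 replicates for spline-band calibration, and 3 replicates of a
40-team trial for the MI-vs-CC comparison — sizes chosen so the full suite
runs in minutes on one CPU while keeping Monte-Carlo SEs small relative to
the tolerances tested (e.g. coverage SE ≈ 0.01 at 500 replicates).

Determinism: every stage draws from `numpy` Generators; the pipeline derives
per-stage streams from a master seed and a stable hash of the stage name, and
the randomizer uses per-(week, purpose) streams, so one stage's
configuration cannot silently perturb another's draws.

## Known limitations

- Individual-level MRT estimation is out of scope; the team-week is the unit
  throughout, which ignores within-team heterogeneity.
- No MNAR mechanisms or sensitivity models; missingness is MAR by
  construction and by assumption.
- The leftover rule makes the realized randomization probability
  history-dependent in principle (it depends on the week's coin draws of
  other teams); the default analysis uses the nominal 1/2, with the
  Monte-Carlo realized probability available as an alternative `p`.
- Week-level treatment is binary competition-of-matching-type; opponent
  identity, score trajectories and win/loss outcomes are not modeled.
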