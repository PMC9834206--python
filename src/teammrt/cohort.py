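"""Synthetic intern cohort with a known causal structure.

Emulates a 12-week cluster micro-randomized trial on first-year medical
residents: interns nested in residency programs (institution x specialty),
grouped into competition teams, with daily step counts, sleep minutes and a
1-10 mood score streamed from wearables/app. Treatment (being in a weekly
team competition of a matching type) shifts the outcome by a week-varying
causal excursion effect ``beta0 + beta_week * week``. Missingness is
missing-at-random (driven by the previous day's observed value and baseline
covariates), lowered slightly during competition weeks (an engagement
effect), plus monotone dropout with a hazard that grows over the study.

Everything is deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, StructuralError

# National specialty mix for incoming interns (shares of the cohort).
SPECIALTY_SHARES: dict[str, float] = {
    "internal_medicine": 0.277,
    "surgery": 0.135,
    "pediatrics": 0.121,
    "emergency_medicine": 0.082,
    "psychiatry": 0.071,
    "obgyn": 0.058,
    "anesthesiology": 0.053,
    "family_medicine": 0.044,
    "neurology": 0.028,
    "med_peds": 0.021,
    "transitional": 0.012,
    "other": 0.099,
}

RACE_SHARES: dict[str, float] = {
    "white": 0.538,
    "black": 0.060,
    "hispanic": 0.054,
    "asian": 0.236,
    "arab_middle_eastern": 0.017,
    "other_multiracial": 0.094,
}

# Specialty groups used by the post-stratification step.
SURGICAL_SPECIALTIES = frozenset({"surgery", "obgyn"})

OUTCOMES = ("steps", "sleep_min", "mood")


@dataclass
class SimConfig:
    """Generating parameters of the synthetic trial.

    Treatment effects are causal excursion effects on the week-0 scale with a
    linear per-week slope, matching the time-varying analysis model. Units:
    steps/day, minutes/day, mood points/day; probabilities on [0, 1].
    """

    # population / design
    n_teams: int = 191
    n_institutions: int = 90
    n_weeks: int = 12
    team_size_min: int = 5
    team_size_mean: float = 9.3
    n_small_programs: int = 0          # extra sub-threshold programs (tests)
    small_program_max: int = 4

    # causal excursion effects (week-0 effect, per-week slope)
    beta_steps: tuple[float, float] = (185.3, -14.5)
    beta_sleep: tuple[float, float] = (9.8, -1.9)
    mood_effect: float = 0.02
    intra_institution_offset_steps: float = 0.0
    intra_specialty_offset_steps: float = 0.0
    intra_institution_offset_sleep: float = 0.0
    intra_specialty_offset_sleep: float = 0.0

    # secular weekly trends
    trend_steps: float = -15.8
    trend_sleep: float = 0.0
    trend_mood: float = 0.0

    # baseline (pre-internship) distributions
    baseline_steps_mean: float = 8121.0
    baseline_steps_sd: float = 3228.9
    baseline_steps_floor: float = 500.0
    baseline_sleep_mean: float = 420.6
    baseline_sleep_sd: float = 107.5
    baseline_mood_mean: float = 6.5
    baseline_mood_sd: float = 1.0

    # variance components
    team_sd_steps: float = 250.0
    team_sd_sleep: float = 4.0
    team_sd_mood: float = 0.15
    intern_sd_steps: float = 400.0
    intern_sd_sleep: float = 25.0
    intern_sd_mood: float = 0.4
    day_cv_steps: float = 0.30         # day noise SD = cv * intern mean
    day_sd_sleep: float = 55.0
    day_sd_mood: float = 1.3
    ar1_rho: float = 0.3               # within-intern day-to-day autocorrelation

    # missingness (MAR + engagement uplift + dropout)
    miss_base_steps: float = 0.30
    miss_base_sleep: float = 0.50
    miss_base_mood: float = 0.40
    mar_coef_steps: float = -0.10      # per SD of previous-day outcome
    mar_coef_sleep: float = -0.10
    mar_coef_mood: float = -0.10
    participation_uplift_steps: float = 0.003
    participation_uplift_sleep: float = 0.009
    participation_uplift_mood: float = 0.0
    dropout_hazard0: float = 0.004
    dropout_hazard_slope: float = 0.002

    # demographics
    p_female: float = 0.545
    p_fitbit: float = 0.70
    age_mean: float = 27.6
    age_sd: float = 2.6
    phq9_mean: float = 3.0
    specialty_shares: dict[str, float] = field(
        default_factory=lambda: dict(SPECIALTY_SHARES))
    race_shares: dict[str, float] = field(
        default_factory=lambda: dict(RACE_SHARES))

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("miss_base", "participation_uplift", "p_",
                                  "dropout_hazard0")) and isinstance(v, float):
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{f.name} must be in [0, 1], got {v}")
            if ("_sd" in f.name or f.name.endswith(("_cv_steps",))) and isinstance(v, float):
                if v < 0:
                    raise ConfigError(f"{f.name} must be >= 0, got {v}")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError(f"ar1_rho must be in (-1, 1), got {self.ar1_rho}")
        if self.n_teams < 1:
            raise ConfigError(f"n_teams must be >= 1, got {self.n_teams}")
        if self.n_weeks < 1:
            raise ConfigError(f"n_weeks must be >= 1, got {self.n_weeks}")
        if self.team_size_mean < self.team_size_min:
            raise ConfigError(
                f"team_size_mean must be >= team_size_min, got {self.team_size_mean}")
        for name in ("specialty_shares", "race_shares"):
            shares = getattr(self, name)
            if min(shares.values()) < 0:
                raise ConfigError(f"{name} must be nonnegative")

    # rough total-SD scales used to standardize MAR predictors
    def outcome_scale(self, outcome: str) -> tuple[float, float]:
        if outcome == "steps":
            sd = np.sqrt(self.baseline_steps_sd ** 2
                         + (self.day_cv_steps * self.baseline_steps_mean) ** 2)
            return self.baseline_steps_mean, sd
        if outcome == "sleep_min":
            sd = np.sqrt(self.baseline_sleep_sd ** 2 + self.day_sd_sleep ** 2)
            return self.baseline_sleep_mean, sd
        sd = np.sqrt(self.baseline_mood_sd ** 2 + self.day_sd_mood ** 2)
        return self.baseline_mood_mean, sd


def _normalized(shares: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(shares)
    p = np.asarray([shares[k] for k in keys], dtype=float)
    return keys, p / p.sum()


def simulate_population(config: SimConfig, rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw interns grouped into residency programs.

    Returns ``(interns, teams)``. Teams are obtained by running the actual
    team-formation rule (:func:`teammrt.randomize.form_teams`) on the drawn
    programs, so the population and the team roster are always consistent.
    Ineligible interns (programs/pools below the minimum size) carry
    ``team_id = NaN``.
    """
    from .randomize import form_teams  # local import to avoid a cycle

    config.validate()

    # One program per (institution, specialty) pair, sampled without
    # replacement so program identity is unambiguous.
    spec_keys, spec_p = _normalized(config.specialty_shares)
    pairs: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    max_pairs = config.n_institutions * len(spec_keys)
    n_programs = config.n_teams + config.n_small_programs
    if n_programs > max_pairs:
        raise ConfigError(
            "n_teams + n_small_programs exceeds n_institutions x specialties")
    while len(pairs) < n_programs:
        inst = int(rng.integers(config.n_institutions))
        spec = spec_keys[int(rng.choice(len(spec_keys), p=spec_p))]
        if (inst, spec) not in seen:
            seen.add((inst, spec))
            pairs.append((inst, spec))

    sizes = np.concatenate([
        config.team_size_min
        + rng.poisson(config.team_size_mean - config.team_size_min,
                      size=config.n_teams),
        rng.integers(1, config.small_program_max + 1,
                     size=config.n_small_programs),
    ]).astype(int)

    n = int(sizes.sum())
    inst_ids = np.repeat([p[0] for p in pairs], sizes)
    specs = np.repeat([p[1] for p in pairs], sizes)

    race_keys, race_p = _normalized(config.race_shares)
    baseline_steps = np.maximum(
        rng.normal(config.baseline_steps_mean, config.baseline_steps_sd, n),
        config.baseline_steps_floor)

    # dropout_week = number of weeks with any data (n_weeks+1 => never drops)
    never = config.n_weeks + 1
    dropout = np.full(n, never, dtype=int)
    alive = np.ones(n, dtype=bool)
    for w in range(1, config.n_weeks):
        hazard = min(config.dropout_hazard0 + config.dropout_hazard_slope * w, 1.0)
        drops = alive & (rng.random(n) < hazard)
        dropout[drops] = w
        alive &= ~drops

    interns = pd.DataFrame({
        "intern_id": [f"I{i:05d}" for i in range(n)],
        "institution_id": [f"H{k:03d}" for k in inst_ids],
        "specialty": specs,
        "program_id": [f"H{k:03d}:{s}" for k, s in zip(inst_ids, specs)],
        "sex": np.where(rng.random(n) < config.p_female, "female", "male"),
        "race": rng.choice(race_keys, size=n, p=race_p),
        "age_years": np.maximum(rng.normal(config.age_mean, config.age_sd, n), 18.0),
        "device_type": np.where(rng.random(n) < config.p_fitbit,
                                "fitbit", "apple_watch"),
        "phq9": rng.poisson(config.phq9_mean, n),
        "neuroticism": rng.normal(0.0, 1.0, n),
        "early_family_env": rng.normal(0.0, 1.0, n),
        "baseline_steps": baseline_steps,
        "baseline_sleep": np.clip(
            rng.normal(config.baseline_sleep_mean, config.baseline_sleep_sd, n),
            0.0, 1440.0),
        "baseline_mood": np.clip(
            rng.normal(config.baseline_mood_mean, config.baseline_mood_sd, n),
            1.0, 10.0),
        "dropout_week": dropout,
    })

    teams, team_of, _ineligible = form_teams(interns, min_size=config.team_size_min)
    interns["team_id"] = interns["intern_id"].map(team_of)
    return interns, teams


def _ar1_noise(rng: np.random.Generator, n: int, n_days: int, rho: float) -> np.ndarray:
    """Stationary AR(1) noise matrix with unit marginal variance."""
    eps = rng.standard_normal((n, n_days))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    innov = np.sqrt(1.0 - rho ** 2)
    for d in range(1, n_days):
        x[:, d] = rho * x[:, d - 1] + innov * eps[:, d]
    return x


def _treatment_matrices(interns: pd.DataFrame, assignments: pd.DataFrame,
                        config: SimConfig) -> dict[str, np.ndarray]:
    """Per-intern x per-week treatment/pairing indicator matrices."""
    team_ids = interns["team_id"]
    n, w = len(interns), config.n_weeks
    need = set((t, k) for t in team_ids.dropna().unique() for k in range(w))
    have = set(zip(assignments["team_id"], assignments["week_index"]))
    if not need <= have:
        missing = sorted(need - have)[:3]
        raise StructuralError(f"assignments do not cover all team-weeks, e.g. {missing}")

    a = assignments.set_index(["team_id", "week_index"])
    comp = a["in_competition"].unstack().reindex(columns=range(w))
    ctype = a["competition_type"].unstack().reindex(columns=range(w))
    rule = a["pairing_rule"].unstack().reindex(columns=range(w))

    def expand(team_mat: pd.DataFrame) -> np.ndarray:
        out = np.zeros((n, w))
        member = team_ids.notna().to_numpy()
        idx = team_mat.index.get_indexer(team_ids[member])
        out[member] = team_mat.to_numpy()[idx]
        return out

    in_comp = expand(comp.fillna(False).astype(float))
    a_step = expand((comp.fillna(False) & (ctype == "step")).astype(float))
    a_sleep = expand((comp.fillna(False) & (ctype == "sleep")).astype(float))
    intra_inst = expand((comp.fillna(False) & (rule == "intra_institution")).astype(float))
    intra_spec = expand((comp.fillna(False) & (rule == "intra_specialty")).astype(float))
    return {"any": in_comp, "step": a_step, "sleep": a_sleep,
            "intra_institution": intra_inst, "intra_specialty": intra_spec}


def simulate_outcomes(interns: pd.DataFrame, assignments: pd.DataFrame,
                      config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate complete (no-missingness) daily records for every intern-day.

    Model per intern i, day d in week w:
    ``y = baseline_i + trend*w + team_re + intern_re + A_w*(beta0 + beta_week*w
    + pairing offsets) + AR(1) day noise``, where ``A_w`` indicates a
    competition of the matching type. Mood uses the any-competition indicator
    on a latent Gaussian clipped to [1, 10].
    """
    config.validate()
    n, n_days, n_weeks = len(interns), config.n_days, config.n_weeks
    weeks = np.repeat(np.arange(n_weeks), 7)  # week of each day

    tm = _treatment_matrices(interns, assignments, config)

    team_ids = pd.Index(sorted(interns["team_id"].dropna().unique()))
    team_re = {
        "steps": rng.normal(0.0, config.team_sd_steps, len(team_ids)),
        "sleep_min": rng.normal(0.0, config.team_sd_sleep, len(team_ids)),
        "mood": rng.normal(0.0, config.team_sd_mood, len(team_ids)),
    }
    t_idx = team_ids.get_indexer(interns["team_id"].fillna("__none__"))
    has_team = t_idx >= 0

    def team_effect(outcome: str) -> np.ndarray:
        out = np.zeros(n)
        out[has_team] = team_re[outcome][t_idx[has_team]]
        return out

    def excursion(kind: str, beta: tuple[float, float],
                  off_inst: float, off_spec: float) -> np.ndarray:
        per_week = tm[kind] * (beta[0] + beta[1] * np.arange(n_weeks)
                               + off_inst * tm["intra_institution"]
                               + off_spec * tm["intra_specialty"])
        return per_week[:, weeks]

    # steps
    mean_steps = (interns["baseline_steps"].to_numpy()
                  + rng.normal(0.0, config.intern_sd_steps, n)
                  + team_effect("steps"))
    day_scale = config.day_cv_steps * np.maximum(mean_steps, 1.0)
    steps = (mean_steps[:, None] + config.trend_steps * weeks[None, :]
             + excursion("step", config.beta_steps,
                         config.intra_institution_offset_steps,
                         config.intra_specialty_offset_steps)
             + day_scale[:, None] * _ar1_noise(rng, n, n_days, config.ar1_rho))
    steps = np.maximum(steps, 0.0)

    # sleep
    mean_sleep = (interns["baseline_sleep"].to_numpy()
                  + rng.normal(0.0, config.intern_sd_sleep, n)
                  + team_effect("sleep_min"))
    sleep = (mean_sleep[:, None] + config.trend_sleep * weeks[None, :]
             + excursion("sleep", config.beta_sleep,
                         config.intra_institution_offset_sleep,
                         config.intra_specialty_offset_sleep)
             + config.day_sd_sleep * _ar1_noise(rng, n, n_days, config.ar1_rho))
    sleep = np.clip(sleep, 0.0, 1440.0)

    # mood (latent Gaussian, any-competition effect, clipped to the 1-10 scale)
    mean_mood = (interns["baseline_mood"].to_numpy()
                 + rng.normal(0.0, config.intern_sd_mood, n)
                 + team_effect("mood"))
    mood = (mean_mood[:, None] + config.trend_mood * weeks[None, :]
            + config.mood_effect * tm["any"][:, weeks]
            + config.day_sd_mood * _ar1_noise(rng, n, n_days, config.ar1_rho))
    mood = np.clip(mood, 1.0, 10.0)

    return pd.DataFrame({
        "intern_id": np.repeat(interns["intern_id"].to_numpy(), n_days),
        "day_index": np.tile(np.arange(n_days), n),
        "steps": steps.ravel(),
        "sleep_min": sleep.ravel(),
        "mood": mood.ravel(),
    })


def apply_missingness(records: pd.DataFrame, interns: pd.DataFrame,
                      assignments: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank outcomes under MAR + engagement uplift + dropout.

    The day-d missingness probability for an outcome is
    ``base + mar_coef * z - uplift * A_any``, clipped to [0, 1], where ``z``
    is the standardized previous-day value *if that day was observed*, else
    the standardized intern baseline — so the mechanism depends only on
    observed data (MAR by construction). Dropout blanks all outcomes from the
    intern's ``dropout_week`` onward (0-based weeks ``>= dropout_week``).

    Returns ``(observed, complete)``: the masked copy and the untouched input.
    """
    config.validate()
    n, n_days = len(interns), config.n_days
    complete = records.copy()
    rec = records.sort_values(["intern_id", "day_index"])
    if len(rec) != n * n_days:
        raise StructuralError("records must form a full intern x day grid")

    tm = _treatment_matrices(interns, assignments, config)
    a_any = tm["any"][:, np.repeat(np.arange(config.n_weeks), 7)]

    dropout = interns["dropout_week"].to_numpy()
    week_of_day = np.arange(n_days) // 7
    dropped = week_of_day[None, :] >= dropout[:, None]

    baselines = {"steps": interns["baseline_steps"].to_numpy(),
                 "sleep_min": interns["baseline_sleep"].to_numpy(),
                 "mood": interns["baseline_mood"].to_numpy()}
    params = {"steps": (config.miss_base_steps, config.mar_coef_steps,
                        config.participation_uplift_steps),
              "sleep_min": (config.miss_base_sleep, config.mar_coef_sleep,
                            config.participation_uplift_sleep),
              "mood": (config.miss_base_mood, config.mar_coef_mood,
                       config.participation_uplift_mood)}

    out = {}
    for outcome in OUTCOMES:
        y = rec[outcome].to_numpy().reshape(n, n_days)
        base, coef, uplift = params[outcome]
        mu, sd = config.outcome_scale(outcome)
        z_base = (baselines[outcome] - mu) / sd
        miss = np.zeros((n, n_days), dtype=bool)
        z_prev = z_base
        for d in range(n_days):
            p = np.clip(base + coef * z_prev - uplift * a_any[:, d], 0.0, 1.0)
            miss[:, d] = rng.random(n) < p
            obs_today = ~miss[:, d]
            z_today = (y[:, d] - mu) / sd
            z_prev = np.where(obs_today, z_today, z_base)
        miss |= dropped
        out[outcome] = np.where(miss.ravel(), np.nan, y.ravel())

    observed = rec.copy()
    for outcome in OUTCOMES:
        observed[outcome] = out[outcome]
    observed = observed.sort_index()
    return observed, complete
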