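"""Synthetic cohort generator: determinism, structure, missingness targets."""

import numpy as np
import pandas as pd
import pytest

import teammrt as tm
from teammrt.cohort import SimConfig
from teammrt.exceptions import ConfigError


def test_degenerate_single_program():
    cfg = SimConfig(n_teams=1, n_institutions=1,
                    specialty_shares={"psychiatry": 1.0},
                    team_size_mean=10.0)
    interns, teams = tm.simulate_population(cfg, np.random.default_rng(0))
    assert interns["program_id"].nunique() == 1
    assert len(teams) == 1
    assert (interns["team_id"] == teams["team_id"].iloc[0]).all()


def test_default_config_matches_study_size():
    interns, teams = tm.simulate_population(SimConfig(), np.random.default_rng(7))
    assert abs(len(teams) - 191) <= 5
    assert abs(len(interns) - 1779) <= 150
    assert interns["specialty"].nunique() == 12
    # specialty margins near their configured targets
    got = interns["specialty"].value_counts(normalize=True)
    for spc, share in SimConfig().specialty_shares.items():
        assert abs(got.get(spc, 0.0) - share / 1.001) < 0.05


def test_population_determinism():
    a = tm.simulate_population(SimConfig(n_teams=15), np.random.default_rng(3))
    b = tm.simulate_population(SimConfig(n_teams=15), np.random.default_rng(3))
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])


def test_intern_invariants(small_trial):
    interns = small_trial["interns"]
    assert (interns["baseline_steps"] >= 0).all()
    assert interns["baseline_sleep"].between(0, 1440).all()
    assert interns["dropout_week"].between(1, 13).all()
    assert interns.groupby("intern_id")["program_id"].nunique().eq(1).all()


@pytest.mark.parametrize("field,value", [
    ("miss_base_steps", 1.5), ("team_sd_steps", -1.0), ("ar1_rho", 1.2),
    ("n_teams", 0),
])
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(ConfigError, match=field):
        cfg.validate()


def test_noiseless_identity():
    """With all noise off, beta0=100 and no trend/decay, each step-competition
    day exceeds the matched non-competition day by exactly 100 steps."""
    cfg = SimConfig(n_teams=6, n_institutions=3, beta_steps=(100.0, 0.0),
                    beta_sleep=(0.0, 0.0), mood_effect=0.0,
                    trend_steps=0.0, trend_sleep=0.0,
                    team_sd_steps=0.0, team_sd_sleep=0.0, team_sd_mood=0.0,
                    intern_sd_steps=0.0, intern_sd_sleep=0.0, intern_sd_mood=0.0,
                    day_cv_steps=0.0, day_sd_sleep=0.0, day_sd_mood=0.0,
                    baseline_steps_sd=0.0, baseline_sleep_sd=0.0,
                    baseline_mood_sd=0.0)
    rng = np.random.default_rng(1)
    interns, teams = tm.simulate_population(cfg, rng)
    assignments = tm.randomize_weeks(teams, cfg.n_weeks, seed=2)
    rec = tm.simulate_outcomes(interns, assignments, cfg, rng)
    rec = rec.merge(interns[["intern_id", "team_id"]], on="intern_id")
    rec["week_index"] = rec["day_index"] // 7
    merged = rec.merge(assignments, on=["team_id", "week_index"])
    a_step = merged["in_competition"] & (merged["competition_type"] == "step")
    assert np.allclose(merged.loc[a_step, "steps"], 8121.0 + 100.0)
    assert np.allclose(merged.loc[~a_step, "steps"], 8121.0)


def test_missing_fractions_near_targets():
    """MAR-only missingness (no dropout) hits the configured daily rates."""
    cfg = SimConfig(n_teams=120, dropout_hazard0=0.0, dropout_hazard_slope=0.0,
                    participation_uplift_steps=0.0,
                    participation_uplift_sleep=0.0)
    rng = np.random.default_rng(12)
    interns, teams = tm.simulate_population(cfg, rng)
    assert len(interns) >= 1000
    assignments = tm.randomize_weeks(teams, cfg.n_weeks, seed=12)
    rec = tm.simulate_outcomes(interns, assignments, cfg, rng)
    obs, _ = tm.apply_missingness(rec, interns, assignments, cfg, rng)
    assert abs(obs["steps"].isna().mean() - 0.30) < 0.02
    assert abs(obs["sleep_min"].isna().mean() - 0.50) < 0.02
    assert obs["sleep_min"].isna().mean() > obs["steps"].isna().mean()


def test_zero_missingness_config(small_trial):
    cfg = SimConfig(n_teams=5, n_institutions=3, miss_base_steps=0.0,
                    miss_base_sleep=0.0, miss_base_mood=0.0,
                    mar_coef_steps=0.0, mar_coef_sleep=0.0, mar_coef_mood=0.0,
                    participation_uplift_steps=0.0,
                    participation_uplift_sleep=0.0,
                    dropout_hazard0=0.0, dropout_hazard_slope=0.0)
    rng = np.random.default_rng(5)
    interns, teams = tm.simulate_population(cfg, rng)
    assignments = tm.randomize_weeks(teams, cfg.n_weeks, seed=5)
    rec = tm.simulate_outcomes(interns, assignments, cfg, rng)
    obs, _ = tm.apply_missingness(rec, interns, assignments, cfg, rng)
    assert obs[["steps", "sleep_min", "mood"]].notna().all().all()


def test_forced_dropout_blanks_tail_weeks():
    cfg = SimConfig(n_teams=4, n_institutions=2, dropout_hazard0=1.0,
                    dropout_hazard_slope=0.0, miss_base_steps=0.0,
                    miss_base_sleep=0.0, miss_base_mood=0.0,
                    mar_coef_steps=0.0, mar_coef_sleep=0.0, mar_coef_mood=0.0,
                    participation_uplift_steps=0.0,
                    participation_uplift_sleep=0.0)
    rng = np.random.default_rng(6)
    interns, teams = tm.simulate_population(cfg, rng)
    assert (interns["dropout_week"] == 1).all()
    assignments = tm.randomize_weeks(teams, cfg.n_weeks, seed=6)
    rec = tm.simulate_outcomes(interns, assignments, cfg, rng)
    obs, _ = tm.apply_missingness(rec, interns, assignments, cfg, rng)
    week = obs["day_index"] // 7
    assert obs.loc[week >= 1, "steps"].isna().all()
    assert obs.loc[week == 0, "steps"].notna().all()


def test_null_effects_balance_arms():
    """With all effect parameters zero, competition and non-competition
    team-week means are exchangeable (location difference ~ 0)."""
    cfg = SimConfig(n_teams=80, beta_steps=(0.0, 0.0), beta_sleep=(0.0, 0.0),
                    mood_effect=0.0)
    tw = tm.simulate_trial_table(cfg, seed=99)
    comp = tw["in_competition"].astype(bool)
    diff = tw.loc[comp, "mean_daily_steps"].mean() - tw.loc[~comp, "mean_daily_steps"].mean()
    pooled_se = tw["mean_daily_steps"].std() * np.sqrt(1 / comp.sum() + 1 / (~comp).sum())
    assert abs(diff) < 4 * pooled_se


def test_missingness_returns_complete_copy(small_trial):
    obs, complete = tm.apply_missingness(
        small_trial["complete"], small_trial["interns"],
        small_trial["assignments"], small_trial["config"],
        np.random.default_rng(0))
    assert complete[["steps", "sleep_min", "mood"]].notna().all().all()
    mask = obs["steps"].notna()
    assert np.allclose(obs.loc[mask, "steps"], complete.loc[mask, "steps"])
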