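import numpy as np
import pandas as pd
import pytest

import teammrt as tm


@pytest.fixture(scope="session")
def small_config() -> tm.SimConfig:
    return tm.SimConfig(n_teams=20, n_institutions=10)


@pytest.fixture(scope="session")
def small_trial(small_config):
    """One small simulated trial: population, assignments, complete and
    observed records, and the team-week table from complete data."""
    rng = np.random.default_rng(42)
    interns, teams = tm.simulate_population(small_config, rng)
    assignments = tm.randomize_weeks(teams[teams["eligible"]],
                                     small_config.n_weeks, seed=42)
    complete = tm.simulate_outcomes(interns, assignments, small_config,
                                    np.random.default_rng(43))
    observed, _ = tm.apply_missingness(complete, interns, assignments,
                                       small_config, np.random.default_rng(44))
    team_week = tm.aggregate_team_week(complete, interns, assignments)
    return {"config": small_config, "interns": interns, "teams": teams,
            "assignments": assignments, "complete": complete,
            "observed": observed, "team_week": team_week}


def make_roster(spec: list[tuple[str, str, int]]) -> pd.DataFrame:
    """Hand-built intern roster from (institution, specialty, count) triples."""
    rows = []
    k = 0
    for inst, spc, n in spec:
        for _ in range(n):
            rows.append({"intern_id": f"I{k:04d}", "institution_id": inst,
                         "specialty": spc, "program_id": f"{inst}:{spc}"})
            k += 1
    return pd.DataFrame(rows)


@pytest.fixture
def roster_factory():
    return make_roster


def tiny_inputs(steps_matrix, n_weeks=1):
    """Five-member single-team trial from an (n x 7*n_weeks) step matrix
    (NaN = missing); sleep and mood constant."""
    steps = np.asarray(steps_matrix, dtype=float)
    n, d = steps.shape
    interns = pd.DataFrame({
        "intern_id": [f"I{i}" for i in range(n)],
        "institution_id": "H1", "specialty": "surgery",
        "program_id": "H1:surgery", "team_id": "T0",
        "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
        "baseline_steps": 8000.0, "baseline_sleep": 420.0,
        "baseline_mood": 7.0, "phq9": 3,
    })
    records = pd.DataFrame({
        "intern_id": np.repeat(interns["intern_id"], d),
        "day_index": np.tile(np.arange(d), n),
        "steps": steps.ravel(),
        "sleep_min": 400.0, "mood": 7.0,
    })
    assignments = pd.DataFrame({
        "team_id": "T0", "week_index": range(n_weeks), "in_competition": False,
        "pairing_rule": None, "opponent_team_id": None,
        "competition_type": None, "leftover": False,
    })
    return records, interns, assignments
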