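#!/usr/bin/env python
"""Generate the default-scale synthetic trial and summarize its structure.

Writes the cohort, team roster, weekly assignments and daily records under
results/trial/, plus a one-row structure summary. Expected shape: ~1779
interns in ~191 teams across 90 institutions and 12 specialties, >30% of
step days and >50% of sleep days missing.
"""

import json
from pathlib import Path

import numpy as np

import teammrt as tm
from teammrt.pipeline import stage_rng, stage_seed

OUT = Path(__file__).resolve().parent.parent / "results" / "trial"
SEED = 20_260_915

def main() -> None:
    cfg = tm.SimConfig()
    interns, teams = tm.simulate_population(cfg, stage_rng(SEED, "population"))
    assignments = tm.randomize_weeks(teams[teams["eligible"]], cfg.n_weeks,
                                     stage_seed(SEED, "randomize"))
    records = tm.simulate_outcomes(interns, assignments, cfg,
                                   stage_rng(SEED, "outcomes"))
    observed, _ = tm.apply_missingness(records, interns, assignments, cfg,
                                       stage_rng(SEED, "missingness"))

    OUT.mkdir(parents=True, exist_ok=True)
    interns.to_csv(OUT / "interns.csv", index=False)
    teams.to_csv(OUT / "teams.csv", index=False)
    assignments.to_csv(OUT / "assignments.csv", index=False)
    observed.to_csv(OUT / "daily_records.csv", index=False)

    miss_by_week = (observed.assign(week=observed["day_index"] // 7)
                    .groupby("week")[["steps", "sleep_min"]]
                    .apply(lambda g: g.isna().mean()))
    summary = {
        "seed": SEED,
        "n_interns": int(len(interns)),
        "n_teams": int(len(teams)),
        "n_institutions": int(interns["institution_id"].nunique()),
        "n_specialties": int(interns["specialty"].nunique()),
        "missing_steps": float(observed["steps"].isna().mean()),
        "missing_sleep": float(observed["sleep_min"].isna().mean()),
        "missing_mood": float(observed["mood"].isna().mean()),
        "missing_steps_week0": float(miss_by_week.loc[0, "steps"]),
        "missing_steps_week11": float(miss_by_week.loc[11, "steps"]),
    }
    (OUT / "structure.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(f"\nwrote trial data to {OUT}")

if __name__ == "__main__":
    main()
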