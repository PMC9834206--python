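#!/usr/bin/env python
"""Robustness analyses on one synthetic trial.

(1) Spline (penalized, REML) vs natural-cubic vs linear week-varying effect
    curves for steps; (2) complete-case variants (dropout filter; weekly
    missingness filter at >5 missing person-days); (3) multiple imputation vs
    complete case, side by side with standardized differences.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import teammrt as tm
from teammrt.impute import ImputationSpec
from teammrt.pipeline import stage_rng, stage_seed

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_260_917

def main() -> None:
    cfg = tm.SimConfig(n_teams=60, n_institutions=30)
    interns, teams = tm.simulate_population(cfg, stage_rng(SEED, "population"))
    assignments = tm.randomize_weeks(teams[teams["eligible"]], cfg.n_weeks,
                                     stage_seed(SEED, "randomize"))
    records = tm.simulate_outcomes(interns, assignments, cfg,
                                   stage_rng(SEED, "outcomes"))
    observed, _ = tm.apply_missingness(records, interns, assignments, cfg,
                                       stage_rng(SEED, "missingness"))
    OUT.mkdir(parents=True, exist_ok=True)

    # --- MI pipeline
    sets = tm.impute_pmm(observed, interns, ImputationSpec(m=10, n_sweeps=5),
                         stage_rng(SEED, "impute"))
    tables = [tm.aggregate_team_week(s, interns, assignments) for s in sets]
    mi_fits = [tm.fit_moderation_week(t, "steps") for t in tables]
    mi_table = tm.pool_fits(mi_fits)

    # --- effect curves on the first completed dataset
    curves = []
    for basis in ("penalized", "natural_cubic"):
        c = tm.fit_spline_moderation(tables[0], "steps",
                                     tm.SplineSpec(basis=basis, df=4))
        c["basis"] = basis
        curves.append(c)
    lin = tm.fit_moderation_week(tables[0], "steps")
    b0 = lin.estimate("competition").estimate
    b1 = lin.estimate("competition:week").estimate
    linear = pd.DataFrame({"week": np.arange(12.0),
                           "estimate": b0 + b1 * np.arange(12.0),
                           "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                           "basis": "linear"})
    pd.concat(curves + [linear]).to_csv(OUT / "effect_curves.csv", index=False)

    # --- complete-case variants
    cc_tw = tm.aggregate_team_week(observed, interns, assignments)
    cc_fit = tm.fit_moderation_week(cc_tw, "steps")
    cc_table = cc_fit.to_frame().rename(columns={"p_value": "p"})

    dropout_sets = [tm.complete_case_dropout(s, observed) for s in sets]
    drop_fits = [tm.fit_moderation_week(
        tm.aggregate_team_week(s, interns, assignments), "steps")
        for s in dropout_sets]
    drop_table = tm.pool_fits(drop_fits)

    # at ~30% daily missingness the strict >5-person-day rule removes almost
    # every team-week; report it alongside a quartile-scaled threshold
    n_strict = len(tm.complete_case_weekly(cc_tw, observed, interns, "steps",
                                           max_missing_per_week=5))
    weekly_tw = tm.complete_case_weekly(cc_tw, observed, interns, "steps",
                                        max_missing_per_week=25)
    weekly_fit = tm.fit_moderation_week(weekly_tw, "steps")
    weekly_table = weekly_fit.to_frame().rename(columns={"p_value": "p"})

    # --- MI vs CC comparison
    comparison = tm.compare_mi_vs_cc(mi_table, cc_table)
    comparison.to_csv(OUT / "mi_vs_cc.csv", index=False)

    eff = lambda t: t.set_index("term").loc["competition", ["estimate", "se"]]
    print("Week-0 step effect (generating value 185.3):")
    print("  multiple imputation:", eff(mi_table).round(1).to_dict())
    print("  complete case:      ", eff(cc_table).round(1).to_dict())
    print("  dropout-filtered MI:", eff(drop_table).round(1).to_dict())
    print("  weekly-filtered CC: ", eff(weekly_table).round(1).to_dict(),
          f"({len(weekly_tw)} of {len(cc_tw)} team-weeks at threshold 25;")
    print(f"   the strict >5-person-day rule would retain {n_strict})")
    print("\nMI vs CC standardized differences:")
    print(comparison[comparison["term"].str.startswith("competition")]
          .round(2).to_string(index=False))

if __name__ == "__main__":
    main()
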