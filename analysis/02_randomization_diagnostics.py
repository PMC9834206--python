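#!/usr/bin/env python
"""Design diagnostics of the weekly three-factor randomization.

Over many simulated weeks of a fixed roster: empirical frequency of each
pairing rule (design: 1/3 each), competition-type split among realized pairs
(design: 50/50), per-team realized competition probability (below the nominal
1/2 because of the odd-leftover rule), and the leftover rate.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import teammrt as tm
from teammrt.randomize import randomize_week

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7
N_WEEKS = 10_000

def roster(n=20):
    specs = ["internal_medicine", "surgery", "pediatrics", "emergency_medicine"]
    return pd.DataFrame({"team_id": [f"T{i:02d}" for i in range(n)],
                         "institution_id": [f"H{i % 7}" for i in range(n)],
                         "specialty": [specs[i % 4] for i in range(n)],
                         "kind": "program", "n_members": 9, "eligible": True})

def main() -> None:
    teams = roster()
    rule_counts = {}
    n_pairs = n_step = n_leftover = 0
    comp_weeks = np.zeros(len(teams))
    for w in range(N_WEEKS):
        a = randomize_week(teams, w, np.random.SeedSequence([SEED, w]))
        comp = a[a["in_competition"]]
        if len(comp):
            rule = comp["pairing_rule"].iloc[0]
            rule_counts[rule] = rule_counts.get(rule, 0) + 1
        n_pairs += len(comp) // 2
        n_step += int((comp["competition_type"] == "step").sum()) // 2
        n_leftover += int(a["leftover"].sum())
        comp_weeks += a.sort_values("team_id")["in_competition"].to_numpy()

    p_team = comp_weeks / N_WEEKS
    out = {
        "n_weeks": N_WEEKS,
        "rule_frequencies": {k: v / sum(rule_counts.values())
                             for k, v in sorted(rule_counts.items())},
        "step_type_share_pct": 100.0 * n_step / n_pairs,
        "n_realized_pairs": n_pairs,
        "leftover_rate_per_week": n_leftover / N_WEEKS,
        "realized_competition_probability": {
            "mean": float(p_team.mean()), "min": float(p_team.min()),
            "max": float(p_team.max()), "nominal": 0.5,
        },
    }
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "randomization_diagnostics.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))

if __name__ == "__main__":
    main()
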