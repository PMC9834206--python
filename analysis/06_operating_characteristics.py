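#!/usr/bin/env python
"""Monte-Carlo operating characteristics of the WCLS estimator.

Repeats a 150-team, 12-week trial (step effect 185.3 with slope -14.5; sleep
effect null) and reports bias, RMSE, 95% CI coverage and Wald rejection rates
for the week-moderated fit. 200 replicates here; the acceptance suite runs
500.
"""

from pathlib import Path

import teammrt as tm

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_260_918
N_REPS = 200

def main() -> None:
    sim = tm.SimConfig(n_teams=150, beta_sleep=(0.0, 0.0))
    oc = tm.replicate_study(sim, N_REPS, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    oc.to_csv(OUT / "operating_characteristics.csv", index=False)
    print(oc.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nsleep terms are generated null: their rejection_rate is the "
          "type-I error of the Wald test; step rows show bias/coverage.")

if __name__ == "__main__":
    main()
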