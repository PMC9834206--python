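"""Collapse intern-day records to the team-week analysis table.

The team-week is the unit of all inference. Weekly outcome summaries are the
mean of per-member weekly means over members with at least one observed day
(each intern contributes equally); a pooled person-day mean is available via
``method="pooled"`` — after imputation the two coincide. Participation rates
use all randomized members in the denominator, so dropouts count as
non-participating days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import StructuralError

OUTCOME_COLS = {"steps": "mean_daily_steps",
                "sleep_min": "mean_daily_sleep_min",
                "mood": "mean_mood"}

TEAM_WEEK_COLUMNS = [
    "team_id", "week_index", "mean_daily_steps", "mean_daily_sleep_min",
    "mean_mood", "participation_rate_steps", "participation_rate_sleep",
    "participation_rate_mood", "pct_female", "baseline_mean_steps",
    "baseline_mean_sleep", "baseline_mean_phq9", "prev_week_steps",
    "prev_week_sleep_min", "prev_week_mood", "prev_from_baseline", "week",
    "in_competition", "competition_type", "pairing_rule", "leftover",
    "intra_institution", "intra_specialty", "n_members",
]


def aggregate_team_week(records: pd.DataFrame, interns: pd.DataFrame,
                        assignments: pd.DataFrame,
                        method: str = "member_mean") -> pd.DataFrame:
    """Build the team-week table consumed by the estimators.

    ``records`` is the long intern-day table (NaN = missing); ``interns``
    carries team membership and baseline covariates; ``assignments`` the
    weekly treatment states. Outcome means are NaN for a team-week with zero
    observed days (participation 0). Previous-week outcome controls lag by
    one week; at week 0 they fall back to the team's baseline means and
    ``prev_from_baseline`` flags those rows.
    """
    if method not in ("member_mean", "pooled"):
        raise ValueError(f"unknown aggregation method {method!r}")

    members = interns[interns["team_id"].notna()]
    sizes = members.groupby("team_id").size()
    if (sizes == 0).any():
        raise StructuralError("team with zero members")

    rec = records.merge(members[["intern_id", "team_id"]], on="intern_id",
                        how="inner").copy()
    rec["week_index"] = rec["day_index"] // 7
    n_weeks = int(rec["week_index"].max()) + 1

    grid = pd.MultiIndex.from_product([sizes.index, range(n_weeks)],
                                      names=["team_id", "week_index"])

    if method == "member_mean":
        per_member = rec.groupby(["team_id", "week_index", "intern_id"],
                                 observed=True)[list(OUTCOME_COLS)].mean()
        means = (per_member.groupby(["team_id", "week_index"]).mean()
                 .reindex(grid))
    else:
        means = (rec.groupby(["team_id", "week_index"])[list(OUTCOME_COLS)]
                 .mean().reindex(grid))
    means = means.rename(columns=OUTCOME_COLS)

    obs_days = (rec.groupby(["team_id", "week_index"])[list(OUTCOME_COLS)]
                .count().reindex(grid, fill_value=0))
    denom = (7 * sizes).reindex(grid.get_level_values("team_id")).to_numpy()
    part = pd.DataFrame(
        {f"participation_rate_{k.split('_')[0]}": obs_days[k].to_numpy() / denom
         for k in OUTCOME_COLS},
        index=grid)
    # column names: steps -> participation_rate_steps, sleep_min -> ..._sleep,
    # mood -> ..._mood

    base = members.groupby("team_id").agg(
        pct_female=("sex", lambda s: float(np.mean(s == "female"))),
        baseline_mean_steps=("baseline_steps", "mean"),
        baseline_mean_sleep=("baseline_sleep", "mean"),
        baseline_mean_phq9=("phq9", "mean"),
        baseline_mean_mood=("baseline_mood", "mean"),
        n_members=("intern_id", "size"),
    )

    tw = means.join(part).reset_index().merge(base.reset_index(), on="team_id")

    # previous-week outcome controls (week 0 <- team baseline means)
    tw = tw.sort_values(["team_id", "week_index"]).reset_index(drop=True)
    lag_src = {"mean_daily_steps": ("prev_week_steps", "baseline_mean_steps"),
               "mean_daily_sleep_min": ("prev_week_sleep_min", "baseline_mean_sleep"),
               "mean_mood": ("prev_week_mood", "baseline_mean_mood")}
    for col, (lag_col, base_col) in lag_src.items():
        lag = tw.groupby("team_id")[col].shift(1)
        tw[lag_col] = lag.where(tw["week_index"] > 0, tw[base_col])
    tw["prev_from_baseline"] = tw["week_index"] == 0
    tw["week"] = tw["week_index"].astype(float)

    a = assignments[["team_id", "week_index", "in_competition", "pairing_rule",
                     "competition_type", "leftover"]]
    tw = tw.merge(a, on=["team_id", "week_index"], how="left", validate="1:1")
    if tw["in_competition"].isna().any():
        bad = tw.loc[tw["in_competition"].isna(), ["team_id", "week_index"]]
        raise StructuralError(
            f"assignments missing for team-weeks, e.g. {bad.iloc[0].tolist()}")
    comp = tw["in_competition"].astype(bool)
    tw["intra_institution"] = (comp & (tw["pairing_rule"] == "intra_institution")).astype(float)
    tw["intra_specialty"] = (comp & (tw["pairing_rule"] == "intra_specialty")).astype(float)

    tw = tw.drop(columns=["baseline_mean_mood"])
    return tw[TEAM_WEEK_COLUMNS]
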