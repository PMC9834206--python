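"""Team formation and the weekly three-factor competition randomization.

Each Monday every eligible team independently enters the competition arm with
probability 1/2; one opponent-pairing rule (total / intra-institution /
intra-specialty) is drawn uniformly for the week; competition-arm teams are
paired under that rule; any team left unpaired (the odd leftover, or a team
with no rule-compatible partner) is returned to the non-competition arm and
flagged; finally each realized pair flips a fair coin for the competition
type (step count vs sleep minutes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import StructuralError

PAIRING_RULES = ("total", "intra_institution", "intra_specialty")
MIXED = "MIXED"

ASSIGNMENT_COLUMNS = ["team_id", "week_index", "in_competition", "pairing_rule",
                      "opponent_team_id", "competition_type", "leftover"]


def form_teams(interns: pd.DataFrame, min_size: int = 5
               ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Group interns into program- and institution-based teams.

    Programs (institution x specialty) with at least ``min_size`` members
    become program-based teams. Remaining interns within an institution are
    pooled into one institution-based team (specialty ``MIXED``) if the pool
    reaches ``min_size``; everyone else is ineligible.

    Returns ``(teams, team_of, ineligible_ids)`` where ``team_of`` maps
    intern_id -> team_id.
    """
    teams: list[dict] = []
    team_of: dict[str, str] = {}
    ineligible: list[str] = []
    if len(interns) == 0:
        empty = pd.DataFrame(columns=["team_id", "institution_id", "specialty",
                                      "kind", "n_members", "eligible"])
        return empty, pd.Series(team_of, dtype=object), ineligible

    counter = 0
    for inst, inst_group in interns.groupby("institution_id", sort=True):
        pool: list[str] = []
        for (prog, spec), grp in inst_group.groupby(["program_id", "specialty"],
                                                    sort=True):
            ids = grp["intern_id"].tolist()
            if len(ids) >= min_size:
                tid = f"T{counter:04d}"
                counter += 1
                teams.append({"team_id": tid, "institution_id": inst,
                              "specialty": spec, "kind": "program",
                              "n_members": len(ids), "eligible": True})
                team_of.update({i: tid for i in ids})
            else:
                pool.extend(ids)
        if len(pool) >= min_size:
            tid = f"T{counter:04d}"
            counter += 1
            teams.append({"team_id": tid, "institution_id": inst,
                          "specialty": MIXED, "kind": "institution",
                          "n_members": len(pool), "eligible": True})
            team_of.update({i: tid for i in pool})
        else:
            ineligible.extend(pool)

    teams_df = pd.DataFrame(teams, columns=["team_id", "institution_id",
                                            "specialty", "kind", "n_members",
                                            "eligible"])
    return teams_df, pd.Series(team_of, dtype=object), ineligible


def _purpose_rngs(rng) -> list[np.random.Generator]:
    """Four draw streams (arm coins, rule, shuffle, type coins).

    Accepts a ``SeedSequence`` (independent per-purpose streams, so e.g. the
    rule draw is unaffected by roster size) or an ordinary ``Generator``
    (all purposes consume the one stream in a fixed order).
    """
    if isinstance(rng, np.random.SeedSequence):
        return [np.random.default_rng(s) for s in rng.spawn(4)]
    return [rng] * 4


def _greedy_pairs(order: list[int], compatible) -> tuple[list[tuple[int, int]], list[int]]:
    """Pair teams in shuffle order with the next compatible unpaired team."""
    paired: dict[int, int] = {}
    for i, a in enumerate(order):
        if a in paired:
            continue
        for b in order[i + 1:]:
            if b not in paired and compatible(a, b):
                paired[a] = b
                paired[b] = a
                break
    pairs = [(a, b) for a, b in paired.items() if a < b]
    left = [t for t in order if t not in paired]
    return pairs, left


def randomize_week(teams: pd.DataFrame, week_index: int, rng,
                   rule: str | None = None, per_pair_rule: bool = False
                   ) -> pd.DataFrame:
    """One week of the three-factor randomization; returns assignment rows.

    ``rng`` may be a Generator or a SeedSequence (see :func:`_purpose_rngs`).
    ``rule`` forces the pairing rule (used for design diagnostics); by default
    one rule is drawn uniformly and applied to the whole week. With
    ``per_pair_rule`` each anchor team draws its own rule while searching for
    a partner (non-default variant).
    """
    rng_arm, rng_rule, rng_shuffle, rng_type = _purpose_rngs(rng)
    teams = teams.sort_values("team_id").reset_index(drop=True)
    n = len(teams)
    tid = teams["team_id"].to_numpy()
    inst = teams["institution_id"].to_numpy()
    spec = teams["specialty"].to_numpy()

    rows = {t: {"team_id": t, "week_index": week_index, "in_competition": False,
                "pairing_rule": None, "opponent_team_id": None,
                "competition_type": None, "leftover": False} for t in tid}

    coins = rng_arm.random(n) < 0.5
    week_rule = rule if rule is not None else str(rng_rule.choice(PAIRING_RULES))
    drawn = [i for i in range(n) if coins[i]]

    if len(drawn) < 2:
        for t in drawn:  # a lone drawn team can never be paired
            rows[tid[t]]["leftover"] = True
        return pd.DataFrame([rows[t] for t in tid], columns=ASSIGNMENT_COLUMNS)

    order = [drawn[k] for k in rng_shuffle.permutation(len(drawn))]

    def compatible_under(r: str):
        def ok(a: int, b: int) -> bool:
            if r == "total":
                return True
            if r == "intra_institution":
                return inst[a] == inst[b]
            return spec[a] == spec[b] and spec[a] != MIXED
        return ok

    if per_pair_rule:
        paired: dict[int, int] = {}
        pair_rules: dict[tuple[int, int], str] = {}
        for i, a in enumerate(order):
            if a in paired:
                continue
            r = str(rng_rule.choice(PAIRING_RULES))
            ok = compatible_under(r)
            for b in order[i + 1:]:
                if b not in paired and ok(a, b):
                    paired[a] = b
                    paired[b] = a
                    pair_rules[(min(a, b), max(a, b))] = r
                    break
        pairs = sorted(pair_rules)
        left = [t for t in order if t not in paired]
        rule_of = pair_rules
    else:
        pairs, left = _greedy_pairs(order, compatible_under(week_rule))
        rule_of = {p: week_rule for p in pairs}

    for a, b in pairs:
        ctype = "step" if rng_type.random() < 0.5 else "sleep"
        r = rule_of[(min(a, b), max(a, b))]
        for x, y in ((a, b), (b, a)):
            rows[tid[x]].update(in_competition=True, pairing_rule=r,
                                opponent_team_id=tid[y],
                                competition_type=ctype)
    for t in left:
        rows[tid[t]]["leftover"] = True

    return pd.DataFrame([rows[t] for t in tid], columns=ASSIGNMENT_COLUMNS)


def randomize_weeks(teams: pd.DataFrame, n_weeks: int, seed: int,
                    per_pair_rule: bool = False) -> pd.DataFrame:
    """Randomize ``n_weeks`` consecutive weeks with per-(week, purpose) streams."""
    if (~teams["eligible"]).any():
        raise StructuralError("all teams passed to randomization must be eligible")
    frames = [
        randomize_week(teams, w, np.random.SeedSequence([seed, w]),
                       per_pair_rule=per_pair_rule)
        for w in range(n_weeks)
    ]
    return pd.concat(frames, ignore_index=True)


def realized_treatment_probability(teams: pd.DataFrame, rule: str, n_reps: int,
                                   rng: np.random.Generator) -> pd.DataFrame:
    """Monte-Carlo per-team probability of ending up in a realized competition.

    The leftover rule makes this strictly below the nominal 1/2; the gap
    vanishes as the number of pairable teams grows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tid = teams.sort_values("team_id")["team_id"].to_numpy()
    counts = pd.Series(0, index=tid, dtype=float)
    for _ in range(n_reps):
        a = randomize_week(teams, 0, rng, rule=rule)
        counts += a.set_index("team_id")["in_competition"].reindex(tid).to_numpy()
    p = counts / n_reps
    se = np.sqrt(p * (1 - p) / n_reps)
    return pd.DataFrame({"team_id": tid, "p_competition": p.to_numpy(),
                         "se": se.to_numpy()})
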