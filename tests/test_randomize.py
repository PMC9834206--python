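"""Team formation and the weekly three-factor randomization scheme."""

import numpy as np
import pandas as pd
import pytest

import teammrt as tm
from teammrt.randomize import PAIRING_RULES, randomize_week


def teams_frame(rows):
    df = pd.DataFrame(rows, columns=["team_id", "institution_id", "specialty"])
    df["kind"] = "program"
    df["n_members"] = 8
    df["eligible"] = True
    return df


class TestFormTeams:
    def test_program_and_institution_teams(self, roster_factory):
        roster = roster_factory([("H1", "surgery", 7), ("H1", "psychiatry", 3),
                                 ("H1", "neurology", 2)])
        teams, team_of, ineligible = tm.form_teams(roster)
        assert len(teams) == 2
        prog = teams[teams["kind"] == "program"]
        inst = teams[teams["kind"] == "institution"]
        assert prog["n_members"].tolist() == [7]
        assert inst["n_members"].tolist() == [5]
        assert inst["specialty"].tolist() == ["MIXED"]
        assert ineligible == []
        assert len(team_of) == 12

    def test_small_pool_is_ineligible(self, roster_factory):
        roster = roster_factory([("H1", "surgery", 5), ("H1", "psychiatry", 4)])
        teams, _, ineligible = tm.form_teams(roster)
        assert len(teams) == 1
        assert len(ineligible) == 4

    def test_all_large_programs(self, roster_factory):
        roster = roster_factory([("H1", "surgery", 6), ("H2", "surgery", 9)])
        teams, _, ineligible = tm.form_teams(roster)
        assert (teams["kind"] == "program").all()
        assert ineligible == []

    def test_empty_roster(self):
        teams, team_of, ineligible = tm.form_teams(
            pd.DataFrame(columns=["intern_id", "institution_id", "specialty",
                                  "program_id"]))
        assert len(teams) == 0 and len(team_of) == 0 and ineligible == []


class TestRandomizeWeek:
    def test_two_teams_total_pairing(self):
        teams = teams_frame([("A", "H1", "surgery"), ("B", "H2", "psychiatry")])
        for seed in range(40):
            a = randomize_week(teams, 0, np.random.SeedSequence(seed), rule="total")
            comp = a[a["in_competition"]]
            if len(comp):
                assert len(comp) == 2
                assert set(comp["opponent_team_id"]) == {"A", "B"}
                assert comp["competition_type"].nunique() == 1

    def test_opponent_symmetry_and_matching(self, small_trial):
        """Pairing is always an involution: opponent's opponent is the team,
        and the competition type is shared."""
        a = small_trial["assignments"]
        comp = a[a["in_competition"]].set_index(["week_index", "team_id"])
        for (w, t), row in comp.iterrows():
            opp = comp.loc[(w, row["opponent_team_id"])]
            assert opp["opponent_team_id"] == t
            assert opp["competition_type"] == row["competition_type"]
            assert opp["pairing_rule"] == row["pairing_rule"]
        noncomp = a[~a["in_competition"]]
        assert noncomp["opponent_team_id"].isna().all()
        assert noncomp["competition_type"].isna().all()

    def test_constrained_rules_share_label(self, small_trial):
        a = small_trial["assignments"]
        teams = small_trial["teams"].set_index("team_id")
        comp = a[a["in_competition"]]
        for rule, col in (("intra_institution", "institution_id"),
                          ("intra_specialty", "specialty")):
            sub = comp[comp["pairing_rule"] == rule]
            mine = teams.loc[sub["team_id"], col].to_numpy()
            theirs = teams.loc[sub["opponent_team_id"], col].to_numpy()
            assert (mine == theirs).all()

    def test_unpairable_all_returned(self):
        """Distinct institutions + intra-institution rule: every drawn team is
        returned to non-competition (flagged leftover)."""
        teams = teams_frame([(f"T{i}", f"H{i}", "surgery") for i in range(8)])
        for seed in range(25):
            a = randomize_week(teams, 0, np.random.SeedSequence(seed),
                               rule="intra_institution")
            assert not a["in_competition"].any()

    def test_leftover_fires_iff_odd_drawn_under_total(self):
        teams = teams_frame([(f"T{i}", f"H{i}", "s") for i in range(9)])
        saw_odd = False
        for seed in range(60):
            a = randomize_week(teams, 0, np.random.SeedSequence(seed), rule="total")
            n_drawn = int(a["in_competition"].sum() + a["leftover"].sum())
            assert int(a["leftover"].sum()) == n_drawn % 2
            saw_odd |= n_drawn % 2 == 1
        assert saw_odd

    def test_single_team_never_competes(self):
        teams = teams_frame([("A", "H1", "surgery")])
        p = tm.realized_treatment_probability(teams, "total", 50,
                                              np.random.default_rng(0))
        assert (p["p_competition"] == 0).all()


class TestDesignProperties:
    def test_two_team_probability_quarter(self):
        """Both fair coins must land heads: P(realized competition) = 1/4."""
        teams = teams_frame([("A", "H1", "s"), ("B", "H2", "t")])
        p = tm.realized_treatment_probability(teams, "total", 4000,
                                              np.random.default_rng(1))
        assert np.allclose(p["p_competition"], 0.25, atol=4 * 0.0069)

    def test_probability_approaches_half_from_below(self):
        small = teams_frame([(f"T{i}", f"H{i}", "s") for i in range(4)])
        big = teams_frame([(f"T{i}", f"H{i}", "s") for i in range(40)])
        rng = np.random.default_rng(2)
        p_small = tm.realized_treatment_probability(small, "total", 2000, rng)
        p_big = tm.realized_treatment_probability(big, "total", 2000, rng)
        assert p_small["p_competition"].mean() < p_big["p_competition"].mean()
        assert p_big["p_competition"].mean() < 0.5

    def test_rule_frequencies_uniform(self):
        """Each pairing rule drawn ~1/3 of weeks (chi-square GoF)."""
        from scipy import stats
        teams = teams_frame([(f"T{i}", "H1", "s") for i in range(6)])
        rules = []
        for w in range(1500):
            drawn = randomize_week(teams, w, np.random.SeedSequence([5, w]))
            realized = drawn["pairing_rule"].dropna()
            if len(realized):  # weeks with no realized pair carry no rule label
                rules.append(realized.iloc[0])
        counts = pd.Series(rules).value_counts().reindex(PAIRING_RULES, fill_value=0)
        chi2, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_per_pair_rule_variant_valid(self):
        teams = teams_frame([(f"T{i}", f"H{i % 3}", ["s", "t"][i % 2])
                             for i in range(12)])
        a = randomize_week(teams, 0, np.random.SeedSequence(11),
                           per_pair_rule=True)
        comp = a[a["in_competition"]].set_index("team_id")
        for t, row in comp.iterrows():
            assert comp.loc[row["opponent_team_id"], "opponent_team_id"] == t


def test_randomize_weeks_determinism(small_trial):
    teams = small_trial["teams"]
    a1 = tm.randomize_weeks(teams[teams["eligible"]], 12, seed=42)
    a2 = tm.randomize_weeks(teams[teams["eligible"]], 12, seed=42)
    pd.testing.assert_frame_equal(a1, a2)
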