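"""WCLS estimator: algebraic identities, oracle cross-checks, worked
arithmetic, and error contracts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import teammrt as tm
from teammrt.exceptions import SingularDesignError
from teammrt.wcls import ModelSpec, fit_wcls


def synthetic_table(n_teams=40, n_weeks=12, seed=0, effect=100.0,
                    effect_week=0.0):
    """Direct team-week table with randomized matching-type treatment."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_teams):
        team_re = rng.normal(0, 30)
        base_steps = rng.normal(8000, 500)
        base_sleep = rng.normal(420, 20)
        pct_female = rng.uniform(0.3, 0.8)
        phq9 = rng.uniform(1, 6)
        for w in range(n_weeks):
            a = rng.random() < 0.5
            ctype = "step" if rng.random() < 0.5 else "sleep"
            a_step = a and ctype == "step"
            y = (base_steps + team_re - 10 * w
                 + (effect + effect_week * w) * a_step + rng.normal(0, 80))
            rows.append({
                "team_id": f"T{t:03d}", "week_index": w, "week": float(w),
                "mean_daily_steps": y, "in_competition": a,
                "competition_type": ctype if a else None,
                "pct_female": pct_female, "baseline_mean_steps": base_steps,
                "baseline_mean_sleep": base_sleep, "baseline_mean_phq9": phq9,
                "prev_week_steps": base_steps + rng.normal(0, 60),
                "intra_institution": 0.0, "intra_specialty": 0.0,
            })
    return pd.DataFrame(rows)


class TestIdentities:
    def test_centered_ols_identity(self):
        """With p = p_tilde = 0.5 the WCLS fit equals unweighted OLS on the
        centered treatment column (statsmodels oracle, cluster-robust HC0)."""
        data = synthetic_table(seed=1)
        fit = tm.fit_moderation_week(data, "steps")

        controls = ["pct_female", "baseline_mean_steps", "baseline_mean_sleep",
                    "baseline_mean_phq9", "prev_week_steps", "week"]
        A = ((data["in_competition"]) & (data["competition_type"] == "step")
             ).astype(float).to_numpy()
        X = np.column_stack([np.ones(len(data)), data[controls].to_numpy(),
                             A - 0.5, (A - 0.5) * data["week"].to_numpy()])
        ols = sm.OLS(data["mean_daily_steps"].to_numpy(), X).fit(
            cov_type="cluster",
            cov_kwds={"groups": data["team_id"].to_numpy(),
                      "use_correction": False})
        assert np.allclose(fit.params, ols.params, rtol=0, atol=1e-10)
        assert np.allclose(np.sqrt(np.diag(fit.vcov)), ols.bse,
                           rtol=1e-8, atol=1e-12)

    def test_sandwich_equals_hc0_with_singleton_clusters(self):
        data = synthetic_table(n_teams=150, n_weeks=1, seed=2)
        fit = fit_wcls(data, ModelSpec(outcome="steps",
                                       controls=("baseline_mean_steps",)))
        A = ((data["in_competition"]) & (data["competition_type"] == "step")
             ).astype(float).to_numpy()
        X = np.column_stack([np.ones(len(data)),
                             data["baseline_mean_steps"].to_numpy(), A - 0.5])
        hc0 = sm.OLS(data["mean_daily_steps"].to_numpy(), X).fit(cov_type="HC0")
        assert np.allclose(fit.vcov, hc0.cov_params(), rtol=1e-8)

    def test_nondefault_probabilities_change_weights_not_consistency(self):
        """With randomization independent of history and a constant effect,
        WCLS at any constant (p, p_tilde) still centers on the true effect."""
        data = synthetic_table(n_teams=300, seed=3, effect=100.0)
        est = [fit_wcls(data, ModelSpec(outcome="steps", p=p, p_tilde=pt))
               .estimate("competition").estimate
               for p, pt in ((0.5, 0.5), (0.25, 0.25), (0.25, 0.5))]
        assert np.allclose(est, 100.0, atol=8.0)

    def test_zero_variance_outcome(self):
        data = synthetic_table(n_teams=20, seed=4)
        data["mean_daily_steps"] = 555.0
        fit = fit_wcls(data, ModelSpec(outcome="steps",
                                       controls=("week",)))
        assert fit.params[0] == pytest.approx(555.0)
        assert np.allclose(fit.params[1:], 0.0, atol=1e-9)
        assert np.allclose(np.sqrt(np.diag(fit.vcov)), 0.0, atol=1e-6)


class TestRecovery:
    def test_constant_effect_recovery(self):
        ests = []
        for seed in range(30):
            data = synthetic_table(n_teams=60, seed=100 + seed, effect=100.0)
            ests.append(tm.fit_marginal(data, "steps")
                        .estimate("competition").estimate)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 100.0) < 4 * mc_se

    def test_week0_effect_matches_marginal_when_constant(self):
        data = synthetic_table(n_teams=400, seed=5, effect=100.0)
        marg = tm.fit_marginal(data, "steps").estimate("competition").estimate
        mod = tm.fit_moderation_week(data, "steps")
        week0 = mod.estimate("competition").estimate
        assert abs(week0 - marg) < 3 * mod.estimate("competition").se

    def test_null_moderation_centered_at_zero(self):
        ests = []
        for seed in range(25):
            data = synthetic_table(n_teams=50, seed=300 + seed, effect=80.0)
            rng = np.random.default_rng(seed)
            comp = data["in_competition"].astype(float)
            data["intra_institution"] = comp * (rng.random(len(data)) < 0.3)
            data["intra_specialty"] = (comp * (rng.random(len(data)) < 0.3)
                                       * (1 - data["intra_institution"]))
            fit = tm.fit_moderation_pairing(data, "steps")
            ests.append(fit.estimate("competition:intra_institution").estimate)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 4 * mc_se


class TestPairingModeration:
    def test_intra_institution_offset_recovery(self):
        """Generating a -90 steps/day intra-institution offset through the full
        cohort machinery recovers it within Monte-Carlo error."""
        # concentrated institutions so intra-institution pairs are common
        cfg = tm.SimConfig(n_teams=120, n_institutions=25,
                           beta_steps=(185.3, 0.0), beta_sleep=(0.0, 0.0),
                           intra_institution_offset_steps=-90.0)
        ests, ses = [], []
        for r in range(16):
            if len(ests) == 8:
                break
            tw = tm.simulate_trial_table(cfg, seed=700 + r)
            try:
                fit = tm.fit_moderation_pairing(tw, "steps")
            except SingularDesignError:
                # a trial whose 12 weekly rule draws never picked the
                # intra-institution rule cannot identify the term
                continue
            e = fit.estimate("competition:intra_institution")
            ests.append(e.estimate)
            ses.append(e.se)
        assert len(ests) == 8
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - (-90.0)) < max(4 * mc_se, np.mean(ses))

    def test_degenerate_all_intra_institution(self):
        data = synthetic_table(n_teams=30, seed=6)
        data["intra_institution"] = data["in_competition"].astype(float)
        data["intra_specialty"] = data["in_competition"].astype(float)
        with pytest.raises(SingularDesignError, match="intra"):
            tm.fit_moderation_pairing(data, "steps")


class TestContracts:
    def test_non_binary_treatment_rejected(self):
        data = synthetic_table(n_teams=10, seed=7)
        data["in_competition"] = 0.3
        with pytest.raises(ValueError, match="binary"):
            tm.fit_marginal(data, "steps")

    def test_invalid_probabilities(self):
        data = synthetic_table(n_teams=10, seed=8)
        with pytest.raises(ValueError):
            fit_wcls(data, ModelSpec(outcome="steps", p=0.0))

    def test_rows_with_missing_controls_dropped_and_counted(self):
        data = synthetic_table(n_teams=20, seed=9)
        data.loc[:4, "prev_week_steps"] = np.nan
        fit = tm.fit_marginal(data, "steps")
        assert fit.n_dropped == 5
        assert fit.n_obs == len(data) - 5

    def test_participation_outcome_range_checked(self):
        data = synthetic_table(n_teams=10, seed=10)
        data["participation_rate_steps"] = 1.2
        with pytest.raises(ValueError, match="0, 1"):
            tm.fit_participation_lpm(data, "participation_rate_steps")


class TestWorkedArithmetic:
    @pytest.mark.parametrize("b0,b1,week,expected", [
        (185.3, -14.5, 1, 185.3),
        (185.3, -14.5, 6, 112.8),
        (185.3, -14.5, 12, 25.8),
        (9.8, -1.9, 1, 9.8),
    ])
    def test_effect_at_week(self, b0, b1, week, expected):
        assert tm.effect_at_week(b0, b1, week) == pytest.approx(expected)

    def test_effect_at_week_delta_method(self):
        v = np.array([[4.0, 0.0], [0.0, 1.0]])
        est, se = tm.effect_at_week(10.0, -1.0, 3, vcov=v)
        assert est == pytest.approx(8.0)
        assert se == pytest.approx(np.sqrt(4.0 + 4.0))

    def test_effect_at_week_rejects_week_zero(self):
        with pytest.raises(ValueError):
            tm.effect_at_week(1.0, 1.0, 0)

    @pytest.mark.parametrize("n,rate,days,expected", [
        (1779, 0.003, 7, 37), (1779, 0.009, 7, 112), (1000, 0.0, 7, 0),
    ])
    def test_person_days_gain(self, n, rate, days, expected):
        assert tm.person_days_gain(n, rate, days) == expected

    def test_study_flow_percentages(self):
        assert tm.study_flow([4791, 2286, 1936, 1779]) == [100.0, 47.7, 84.7, 91.9]
        assert tm.study_flow([10, 10]) == [100.0, 100.0]
        with pytest.raises(ValueError):
            tm.study_flow([5, 9])
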