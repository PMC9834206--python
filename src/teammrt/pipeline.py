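"""End-to-end trial orchestration and the simulation-study harness.

``run_trial`` chains simulate -> randomize -> missingness -> impute ->
weights -> aggregate -> fit -> (sensitivity) into one reproducible run keyed
by a single master seed; each stage draws from its own stream derived from
the master seed and the stage name, so editing one stage's configuration
never silently changes another stage's draws. ``replicate_study`` repeats a
scaled trial many times and reports operating characteristics (bias, RMSE,
CI coverage, rejection rates) of the excursion-effect estimators against the
generating values.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import impute as imp
from . import wcls
from .aggregate import aggregate_team_week
from .cohort import SimConfig, apply_missingness, simulate_outcomes, \
    simulate_population
from .impute import ImputationSpec
from .randomize import randomize_weeks
from .weights import sample_margins, team_analysis_weights, two_step_weights

STAGES = ("population", "randomize", "outcomes", "missingness", "impute",
          "weights")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Stage stream: master seed + stable hash of the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())]))


def stage_seed(master_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [master_seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    master_seed: int = 0
    outdir: Path | None = None
    impute_missing: bool = True
    use_weights: bool = True
    margins: dict | None = None        # population margins; None = self-raking
    outcomes: tuple[str, ...] = ("steps", "sleep_min")


def run_trial(config: RunConfig) -> dict:
    """Run the whole pipeline once; returns (and optionally writes) a bundle.

    Bundle keys: interns, teams, assignments, records_observed,
    records_complete, team_week (first completed dataset), weights,
    estimates (marginal + week-moderated fits per outcome, Rubin-pooled over
    imputations when imputation ran, weighted and unweighted), manifest.
    """
    sim = config.sim
    interns, teams = simulate_population(sim, stage_rng(config.master_seed,
                                                        "population"))
    eligible = teams[teams["eligible"]]
    assignments = randomize_weeks(eligible, sim.n_weeks,
                                  stage_seed(config.master_seed, "randomize"))
    complete = simulate_outcomes(interns, assignments, sim,
                                 stage_rng(config.master_seed, "outcomes"))
    observed, complete = apply_missingness(complete, interns, assignments, sim,
                                           stage_rng(config.master_seed,
                                                     "missingness"))

    members = interns[interns["team_id"].notna()]
    margins = config.margins if config.margins is not None \
        else sample_margins(members)
    wdf = two_step_weights(members, margins)
    team_w = team_analysis_weights(wdf, members)

    if config.impute_missing:
        completed_sets = imp.impute_pmm(observed, interns, config.imputation,
                                        stage_rng(config.master_seed, "impute"))
    else:
        completed_sets = [observed]

    tables = [aggregate_team_week(ds, interns, assignments)
              for ds in completed_sets]
    observed_table = aggregate_team_week(observed, interns, assignments)
    for t in tables + [observed_table]:
        t["analysis_weight"] = t["team_id"].map(team_w)

    estimates = []
    for outcome in config.outcomes:
        for label, fitter in (("marginal", wcls.fit_marginal),
                              ("week_moderated", wcls.fit_moderation_week)):
            for wlabel, kw in (("unweighted", {}),
                               ("raked", {"weight_col": "analysis_weight"})):
                if wlabel == "raked" and not config.use_weights:
                    continue
                fits = [fitter(t, outcome, **kw) for t in tables]
                pooled = imp.pool_fits(fits)
                pooled.insert(0, "outcome", outcome)
                pooled.insert(1, "model", label)
                pooled.insert(2, "weighting", wlabel)
                estimates.append(pooled)
    for outcome in ("participation_rate_steps", "participation_rate_sleep"):
        fit = wcls.fit_participation_lpm(observed_table, outcome)
        tab = fit.to_frame().rename(columns={"p_value": "p"})
        tab.insert(0, "outcome", outcome)
        tab.insert(1, "model", "lpm_marginal")
        tab.insert(2, "weighting", "unweighted")
        tab["df"] = np.inf
        tab["between_var"] = 0.0
        estimates.append(tab)
    estimates = pd.concat(estimates, ignore_index=True)

    n_total = len(interns)
    n_grouped = int(interns["team_id"].notna().sum())
    manifest = {
        "master_seed": config.master_seed,
        "config": _config_dict(config),
        "stage_rows": {
            "interns": n_total, "teams": int(len(teams)),
            "assignments": int(len(assignments)),
            "records": int(len(observed)),
            "team_week": int(len(tables[0])),
            "imputations": len(completed_sets),
        },
        "flow_counts": [n_total, n_grouped],
        "flow_percent": wcls.study_flow([n_total, n_grouped]),
    }

    bundle = {"interns": interns, "teams": teams, "assignments": assignments,
              "records_observed": observed, "records_complete": complete,
              "team_week": tables[0], "team_week_observed": observed_table,
              "weights": wdf, "estimates": estimates, "manifest": manifest}
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"]) if d["outdir"] else None
    return d


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    names = {"interns": "interns.csv", "teams": "teams.csv",
             "assignments": "assignments.csv",
             "records_observed": "daily_records.csv",
             "team_week": "team_week.csv", "weights": "weights.csv",
             "estimates": "estimates.csv"}
    for key, fname in names.items():
        bundle[key].to_csv(outdir / fname, index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"],
                                                     indent=2, default=str))


def simulate_trial_table(sim: SimConfig, seed: int,
                         with_missingness: bool = False) -> pd.DataFrame:
    """One simulated trial reduced to its team-week analysis table."""
    interns, teams = simulate_population(sim, stage_rng(seed, "population"))
    assignments = randomize_weeks(teams[teams["eligible"]], sim.n_weeks,
                                  stage_seed(seed, "randomize"))
    records = simulate_outcomes(interns, assignments, sim,
                                stage_rng(seed, "outcomes"))
    if with_missingness:
        records, _ = apply_missingness(records, interns, assignments, sim,
                                       stage_rng(seed, "missingness"))
    return aggregate_team_week(records, interns, assignments)


def replicate_study(sim: SimConfig, n_reps: int, seed: int,
                    outcomes: tuple[str, ...] = ("steps", "sleep_min")
                    ) -> pd.DataFrame:
    """Operating characteristics of the week-moderated WCLS fit.

    Repeats ``simulate -> randomize -> aggregate -> fit`` ``n_reps`` times
    (missingness off: this harness characterizes the estimator). Reports, per
    outcome and term, the mean estimate, bias against the generating value,
    RMSE, 95% CI coverage, Wald rejection rate at 5%, and Monte-Carlo SEs.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    truths = {
        ("steps", "competition"): sim.beta_steps[0],
        ("steps", "competition:week"): sim.beta_steps[1],
        ("sleep_min", "competition"): sim.beta_sleep[0],
        ("sleep_min", "competition:week"): sim.beta_sleep[1],
    }
    rows = []
    for r in range(n_reps):
        table = simulate_trial_table(sim, seed + r)
        for outcome in outcomes:
            fit = wcls.fit_moderation_week(table, outcome)
            for term in fit.effect_terms:
                e = fit.estimate(term)
                rows.append({"rep": r, "outcome": outcome, "term": term,
                             "estimate": e.estimate, "se": e.se,
                             "ci_lo": e.ci_lo, "ci_hi": e.ci_hi,
                             "reject": e.p_value < 0.05})
    raw = pd.DataFrame(rows)

    out = []
    for (outcome, term), grp in raw.groupby(["outcome", "term"]):
        truth = truths[(outcome, term)]
        est = grp["estimate"].to_numpy()
        cover = ((grp["ci_lo"] <= truth) & (truth <= grp["ci_hi"])).to_numpy()
        n = len(grp)
        out.append({
            "outcome": outcome, "term": term, "truth": truth, "n_reps": n,
            "mean_estimate": est.mean(), "bias": est.mean() - truth,
            "mc_se_bias": est.std(ddof=1) / np.sqrt(n),
            "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
            "coverage": cover.mean(),
            "mc_se_coverage": float(np.sqrt(cover.mean() * (1 - cover.mean()) / n)),
            "rejection_rate": grp["reject"].mean(),
        })
    return pd.DataFrame(out)
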