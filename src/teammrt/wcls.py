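"""Weighted-and-centered least squares (WCLS) causal excursion estimation.

The estimand is the proximal causal excursion effect of assigning a team to a
weekly competition: the regression includes control variables with their own
nuisance coefficients and a *centered* treatment indicator ``A - p_tilde``
(optionally interacted with moderators), with per-row weights
``p_tilde / p`` for treated rows and ``(1 - p_tilde)/(1 - p)`` otherwise.
Centering plus weighting makes the treatment-term coefficients consistent for
the excursion effect even when the control part of the model is
misspecified. Variance is the cluster-robust sandwich with the team as the
independence cluster (a GEE with independent working correlation). With the
nominal constant ``p = p_tilde = 1/2`` all weights are one and the fit
reduces exactly to ordinary least squares on a centered treatment column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularDesignError

DEFAULT_CONTROLS = {
    "steps": ("pct_female", "baseline_mean_steps", "baseline_mean_sleep",
              "baseline_mean_phq9", "prev_week_steps", "week"),
    "sleep_min": ("pct_female", "baseline_mean_steps", "baseline_mean_sleep",
                  "baseline_mean_phq9", "prev_week_sleep_min", "week"),
    "mood": ("pct_female", "baseline_mean_steps", "baseline_mean_sleep",
             "baseline_mean_phq9", "prev_week_mood", "week"),
    "participation_rate_steps": ("pct_female", "baseline_mean_steps",
                                 "baseline_mean_sleep", "baseline_mean_phq9",
                                 "week"),
    "participation_rate_sleep": ("pct_female", "baseline_mean_steps",
                                 "baseline_mean_sleep", "baseline_mean_phq9",
                                 "week"),
}

# outcome name -> team-week table column holding it
OUTCOME_COLUMN = {
    "steps": "mean_daily_steps",
    "sleep_min": "mean_daily_sleep_min",
    "mood": "mean_mood",
    "participation_rate_steps": "participation_rate_steps",
    "participation_rate_sleep": "participation_rate_sleep",
}

# outcome -> how the binary treatment is derived from the assignment columns
TREATMENT_RULE = {
    "steps": "step",           # competition of the matching type
    "sleep_min": "sleep",
    "mood": "any",
    "participation_rate_steps": "any",
    "participation_rate_sleep": "any",
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, moderators, controls, design probabilities."""

    outcome: str
    moderators: tuple[str, ...] = ()
    controls: tuple[str, ...] | str = "default"
    p_tilde: float = 0.5
    p: float = 0.5
    weight_col: str | None = None      # optional analysis weights (e.g. raking)
    mancl_derouen: bool = False        # small-sample sandwich correction

    def control_names(self) -> tuple[str, ...]:
        if self.controls == "default":
            try:
                return DEFAULT_CONTROLS[self.outcome]
            except KeyError:
                raise ValueError(
                    f"no default controls for outcome {self.outcome!r}") from None
        return tuple(self.controls)


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    p_value: float


@dataclass
class WCLSFit:
    terms: list[str]
    params: np.ndarray
    vcov: np.ndarray                   # cluster-robust
    estimates: list[EffectEstimate] = field(default_factory=list)
    n_obs: int = 0
    n_clusters: int = 0
    n_dropped: int = 0
    effect_terms: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> EffectEstimate:
        return self.estimates[self.terms.index(term)]

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.estimates])


def treatment_indicator(data: pd.DataFrame, outcome: str) -> np.ndarray:
    """Binary treatment column for an outcome (matching-type competition for
    step/sleep outcomes; any competition for mood and participation)."""
    rule = TREATMENT_RULE.get(outcome, "any")
    raw = data["in_competition"].to_numpy()
    if not np.isin(raw, (0, 1, True, False)).all():
        raise ValueError("treatment indicator in_competition must be binary")
    comp = raw.astype(bool)
    if rule == "any":
        return comp.astype(float)
    return (comp & (data["competition_type"] == rule).to_numpy()).astype(float)


def _wald_rows(terms, params, vcov, z_crit=1.959963984540054) -> list[EffectEstimate]:
    out = []
    for j, t in enumerate(terms):
        se = float(np.sqrt(max(vcov[j, j], 0.0)))
        est = float(params[j])
        if se > 0:
            p = 2.0 * stats.norm.sf(abs(est) / se)
        else:
            p = 0.0 if est != 0 else 1.0
        out.append(EffectEstimate(t, est, se, est - z_crit * se,
                                  est + z_crit * se, float(p)))
    return out


def cluster_sandwich(X: np.ndarray, resid: np.ndarray, w: np.ndarray,
                     clusters: np.ndarray, mancl_derouen: bool = False
                     ) -> np.ndarray:
    """Cluster-robust sandwich covariance for a weighted LS fit.

    ``bread^-1 = X'WX``; the meat sums outer products of per-cluster weighted
    score contributions. No small-sample inflation by default; the
    Mancl-DeRouen correction premultiplies each cluster's residuals by
    ``(I - H_cc)^-1``.
    """
    Xw = X * w[:, None]
    bread = np.linalg.inv(X.T @ Xw)
    k = X.shape[1]
    meat = np.zeros((k, k))
    for c in np.unique(clusters):
        m = clusters == c
        Xc, rc, wc = X[m], resid[m], w[m]
        if mancl_derouen:
            Hcc = Xc @ bread @ (Xc * wc[:, None]).T
            rc = np.linalg.solve(np.eye(len(rc)) - Hcc, rc)
        g = (Xc * wc[:, None]).T @ rc
        meat += np.outer(g, g)
    return bread @ meat @ bread


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns beyond the rank under a pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise SingularDesignError(f"design is rank deficient; collinear terms: {bad}")


def fit_wcls(data: pd.DataFrame, spec: ModelSpec) -> WCLSFit:
    """Fit the WCLS model on a team-week table.

    Rows with a missing outcome, control, or moderator are dropped (counted
    in ``n_dropped``). Raises for a non-binary treatment or a singular
    design.
    """
    if not 0.0 < spec.p < 1.0 or not 0.0 < spec.p_tilde < 1.0:
        raise ValueError("p and p_tilde must be in (0, 1)")
    controls = spec.control_names()
    ycol = OUTCOME_COLUMN.get(spec.outcome, spec.outcome)
    cols = [ycol, *controls, *spec.moderators]
    if spec.weight_col:
        cols.append(spec.weight_col)
    df = data.copy()
    df["_A"] = treatment_indicator(df, spec.outcome)
    keep = df[cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df = df[keep]

    A = df["_A"].to_numpy()
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("treatment indicator must be binary")

    y = df[ycol].to_numpy(dtype=float)
    Ac = A - spec.p_tilde
    design = [np.ones(len(df))]
    names = ["intercept"]
    for c in controls:
        design.append(df[c].to_numpy(dtype=float))
        names.append(c)
    design.append(Ac)
    names.append("competition")
    for mcol in spec.moderators:
        design.append(Ac * df[mcol].to_numpy(dtype=float))
        names.append(f"competition:{mcol}")
    X = np.column_stack(design)
    _check_full_rank(X, names)

    w = np.where(A == 1.0, spec.p_tilde / spec.p,
                 (1.0 - spec.p_tilde) / (1.0 - spec.p))
    if spec.weight_col:
        w = w * df[spec.weight_col].to_numpy(dtype=float)

    # solve on the sqrt-weighted design (better conditioned than the normal
    # equations; exactly OLS when all weights are 1)
    s = np.sqrt(w)
    params = np.linalg.lstsq(X * s[:, None], y * s, rcond=None)[0]
    resid = y - X @ params
    clusters = df["team_id"].to_numpy()
    vcov = cluster_sandwich(X, resid, w, clusters,
                            mancl_derouen=spec.mancl_derouen)

    fit = WCLSFit(terms=names, params=params, vcov=vcov,
                  n_obs=len(df), n_clusters=len(np.unique(clusters)),
                  n_dropped=n_dropped,
                  effect_terms=[t for t in names if t.startswith("competition")])
    fit.estimates = _wald_rows(names, params, vcov)
    return fit


def fit_marginal(data: pd.DataFrame, outcome: str, **kw) -> WCLSFit:
    """Marginal (week-averaged) excursion effect of competition."""
    return fit_wcls(data, ModelSpec(outcome=outcome, **kw))


def fit_moderation_week(data: pd.DataFrame, outcome: str, **kw) -> WCLSFit:
    """Time-varying effect: adds a centered-treatment x week interaction.

    With week coded from 0, the ``competition`` term is the week-0 effect and
    ``competition:week`` the per-week change.
    """
    return fit_wcls(data, ModelSpec(outcome=outcome, moderators=("week",), **kw))


def fit_moderation_pairing(data: pd.DataFrame, outcome: str, **kw) -> WCLSFit:
    """Pairing moderation: intra-institution and intra-specialty interactions.

    The flags are coded 0 in non-competition weeks; they only enter the model
    multiplied by the centered treatment, so that coding is inert for the
    effect terms.
    """
    return fit_wcls(data, ModelSpec(outcome=outcome,
                                    moderators=("intra_institution",
                                                "intra_specialty"), **kw))


def fit_participation_lpm(data: pd.DataFrame, outcome: str, **kw) -> WCLSFit:
    """Linear probability model for a weekly participation rate.

    Runs on the non-imputed table (participation *is* the missingness
    process); coefficients are risk differences on the [0, 1] scale.
    """
    if not outcome.startswith("participation_rate"):
        raise ValueError("outcome must be a participation rate column")
    vals = data[outcome].dropna()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("participation rates must lie in [0, 1]")
    return fit_wcls(data, ModelSpec(outcome=outcome, **kw))


def effect_at_week(beta0: float, beta_week: float, week_number: int,
                   vcov: np.ndarray | None = None
                   ) -> float | tuple[float, float]:
    """Moderated effect at a 1-indexed study week: ``beta0 + beta_week*(w-1)``.

    Coefficients are on the week-from-0 coding, so week_number 1 returns
    ``beta0``. If ``vcov`` (2x2 covariance of the two coefficients) is given,
    also returns the delta-method SE.
    """
    if week_number < 1:
        raise ValueError("week_number is 1-indexed and must be >= 1")
    t = week_number - 1
    est = beta0 + beta_week * t
    if vcov is None:
        return est
    var = vcov[0, 0] + 2 * t * vcov[0, 1] + t * t * vcov[1, 1]
    return est, float(np.sqrt(max(var, 0.0)))


def person_days_gain(n_participants: int, rate_effect: float, days: int = 7) -> int:
    """Extra observed person-days in a fully-treated week of ``days`` days."""
    if not -1.0 <= rate_effect <= 1.0:
        raise ValueError("rate_effect must be in [-1, 1]")
    return int(round(n_participants * rate_effect * days))


def study_flow(counts: list[int]) -> list[float]:
    """Stage-to-stage retention percentages along an exclusion chain.

    The first stage is 100.0; each later stage is its count as a percentage
    of the previous stage's count, rounded to one decimal.
    """
    counts = list(counts)
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("stage counts must be nonincreasing")
    if not counts:
        return []
    out = [100.0]
    for prev, cur in zip(counts, counts[1:]):
        out.append(round(100.0 * cur / prev, 1))
    return out
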