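"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's rules for pooling estimates across completed datasets.

Each of the M datasets is produced by cycling PMM updates over the three
daily outcomes (steps -> sleep -> mood). A PMM update regresses the target on
its predictor set over the originally-observed rows, draws regression
parameters from their Bayesian posterior (proper MI; a bootstrap variant is
available), computes predicted means for observed and missing rows, and
replaces each missing value with the observed value of one of the
``k_donors`` observed rows whose predicted means are closest — so imputations
always lie within the observed support.

Predictors per target: the three previous days of all three outcomes, the
previous week's averages of all three, sex, PHQ-9, neuroticism, early family
environment, and mean-encoded institution and specialty. Lags that cross the
study start fall back to the intern's pre-internship baseline (cohort mean of
observed mood for the mood stream, which has no baseline measure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOMES


@dataclass(frozen=True)
class ImputationSpec:
    m: int = 20                 # number of completed datasets
    n_sweeps: int = 10          # chained-equation cycles per dataset
    k_donors: int = 5           # PMM donor-pool size
    draw: str = "bayes"         # "bayes" (posterior draw) or "bootstrap"

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.draw not in ("bayes", "bootstrap"):
            raise ValueError(f"unknown draw method {self.draw!r}")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of per-imputation (estimate, se) pairs."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    m: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.df) if np.isfinite(self.df) \
            else stats.norm.ppf(0.5 + level / 2)
        return self.estimate - t * self.se, self.estimate + t * self.se

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        t = abs(self.estimate) / self.se
        if np.isfinite(self.df):
            return float(2 * stats.t.sf(t, self.df))
        return float(2 * stats.norm.sf(t))


def pool_rubin(per_imputation: list[tuple[float, float]]) -> PooledEstimate:
    """Combine per-imputation (estimate, se) pairs.

    total variance = W + (1 + 1/M) B; df is Rubin's small-sample formula
    ``(M-1) (1 + W / ((1+1/M) B))^2`` (infinite when B = 0 or M = 1).
    """
    if not per_imputation:
        raise ValueError("per_imputation must be non-empty")
    est = np.asarray([e for e, _ in per_imputation], dtype=float)
    se = np.asarray([s for _, s in per_imputation], dtype=float)
    if not (np.isfinite(est).all() and np.isfinite(se).all()):
        raise ValueError("estimates and SEs must be finite")
    m = len(est)
    qbar = float(est.mean())
    w = float((se ** 2).mean())
    b = float(est.var(ddof=1)) if m > 1 else 0.0
    total = w + (1 + 1 / m) * b
    if m > 1 and b > 0:
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    else:
        df = np.inf
    return PooledEstimate(qbar, w, b, total, float(np.sqrt(total)), df, m)


# ---------------------------------------------------------------------------
# chained PMM
# ---------------------------------------------------------------------------

def _as_grids(records: pd.DataFrame, interns: pd.DataFrame
              ) -> tuple[dict[str, np.ndarray], pd.DataFrame, int]:
    """Pivot the long records to (n_interns x n_days) matrices per outcome."""
    order = interns["intern_id"].to_numpy()
    n_days = int(records["day_index"].max()) + 1
    rec = records.sort_values(["intern_id", "day_index"])
    ids = rec["intern_id"].to_numpy()[::n_days]
    if len(rec) != len(order) * n_days or not (np.sort(ids) == np.sort(order)).all():
        raise ValueError("records must form a full intern x day grid over interns")
    pos = pd.Index(ids).get_indexer(order)
    grids = {}
    for outcome in OUTCOMES:
        mat = rec[outcome].to_numpy(dtype=float).reshape(-1, n_days)
        grids[outcome] = mat[pos]
    return grids, rec, n_days


def _static_predictors(interns: pd.DataFrame, grids: dict[str, np.ndarray]
                       ) -> np.ndarray:
    """Baseline covariates incl. mean-encoded institution and specialty."""
    cols = [
        (interns["sex"] == "female").to_numpy(float),
        interns["phq9"].to_numpy(float),
        interns["neuroticism"].to_numpy(float),
        interns["early_family_env"].to_numpy(float),
        interns["baseline_steps"].to_numpy(float),
        interns["baseline_sleep"].to_numpy(float),
    ]
    # mean-encode the two high-cardinality groupings on each intern's observed
    # step mean (one grouped predictor per factor, not 100 dummies)
    g = grids["steps"]
    n_obs = (~np.isnan(g)).sum(axis=1)
    sums = np.nansum(g, axis=1)
    any_obs = n_obs > 0
    obs_mean = np.where(any_obs, sums / np.maximum(n_obs, 1), np.nan)
    overall = obs_mean[any_obs].mean()
    obs_mean = np.where(any_obs, obs_mean, overall)
    for factor in ("institution_id", "specialty"):
        enc = pd.Series(obs_mean).groupby(interns[factor].to_numpy()).transform("mean")
        cols.append(enc.to_numpy(float))
    return np.column_stack(cols)


def _lag_matrix(grid: np.ndarray, lag: int, fallback: np.ndarray) -> np.ndarray:
    out = np.empty_like(grid)
    out[:, lag:] = grid[:, :-lag] if lag > 0 else grid
    out[:, :lag] = fallback[:, None]
    return out


def _dynamic_predictors(current: dict[str, np.ndarray],
                        fallbacks: dict[str, np.ndarray]) -> np.ndarray:
    """Row-per-(intern, day) lag and previous-week-mean predictors."""
    n, n_days = current["steps"].shape
    blocks = []
    for outcome in OUTCOMES:
        g = current[outcome]
        fb = fallbacks[outcome]
        for lag in (1, 2, 3):
            blocks.append(_lag_matrix(g, lag, fb).ravel())
        wk_means = g.reshape(n, -1, 7).mean(axis=2)         # (n, n_weeks)
        prev_wk = np.concatenate([fb[:, None], wk_means[:, :-1]], axis=1)
        blocks.append(np.repeat(prev_wk, 7, axis=1).ravel())
    return np.column_stack(blocks)


def _pmm_update(y: np.ndarray, X: np.ndarray, obs: np.ndarray, mis: np.ndarray,
                k_donors: int, draw: str, rng: np.random.Generator) -> np.ndarray:
    """One PMM step: return donor values for the missing rows."""
    Xo, yo = X[obs], y[obs]
    n_obs, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, Xo.T @ yo)
    if draw == "bayes":
        resid = yo - Xo @ beta_hat
        dof = max(n_obs - p, 1)
        sigma2 = resid @ resid / stats.chi2.rvs(dof, random_state=rng)
        cov = sigma2 * np.linalg.inv(XtX)
        beta_star = rng.multivariate_normal(beta_hat, cov, method="eigh")
    else:  # bootstrap draw
        idx = rng.integers(n_obs, size=n_obs)
        Xb, yb = Xo[idx], yo[idx]
        beta_star = np.linalg.solve(Xb.T @ Xb + 1e-8 * np.eye(p), Xb.T @ yb)

    pred_obs = Xo @ beta_hat
    pred_mis = X[mis] @ beta_star

    # k-nearest observed predicted means via a sorted window search
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    k = min(k_donors, n_obs)
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n_obs - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(k, size=len(pred_mis))]
    donors = order[cand[np.arange(len(pred_mis)), pick]]
    return yo[donors]


def impute_pmm(records: pd.DataFrame, interns: pd.DataFrame,
               spec: ImputationSpec, rng: np.random.Generator
               ) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed copies of the daily-record table."""
    spec.validate()
    grids, rec_sorted, n_days = _as_grids(records, interns)
    miss = {o: np.isnan(grids[o]) for o in OUTCOMES}
    if all(not m.any() for m in miss.values()):
        return [records.copy() for _ in range(spec.m)]
    for o in OUTCOMES:
        if miss[o].all():
            raise ValueError(f"target {o!r} has no observed rows; unimputable")

    static = _static_predictors(interns, grids)
    static_rows = np.repeat(static, n_days, axis=0)
    fallbacks = {
        "steps": interns["baseline_steps"].to_numpy(float),
        "sleep_min": interns["baseline_sleep"].to_numpy(float),
        "mood": np.full(len(interns), np.nanmean(grids["mood"])),
    }
    obs_vals = {o: grids[o][~miss[o]] for o in OUTCOMES}

    order = interns["intern_id"].to_numpy()
    out_frames = []
    for _ in range(spec.m):
        current = {o: grids[o].copy() for o in OUTCOMES}
        for o in OUTCOMES:  # initialize from the observed marginal
            current[o][miss[o]] = rng.choice(obs_vals[o], size=miss[o].sum())
        for _sweep in range(spec.n_sweeps):
            for o in OUTCOMES:
                if not miss[o].any():
                    continue
                dyn = _dynamic_predictors(current, fallbacks)
                X = np.column_stack([np.ones(len(dyn)), dyn, static_rows])
                y = current[o].ravel()
                obs_flat = ~miss[o].ravel()
                donors = _pmm_update(y, X, obs_flat, ~obs_flat,
                                     spec.k_donors, spec.draw, rng)
                cur = current[o].ravel()
                cur[~obs_flat] = donors
                current[o] = cur.reshape(grids[o].shape)
        done = pd.DataFrame({
            "intern_id": np.repeat(order, n_days),
            "day_index": np.tile(np.arange(n_days), len(order)),
            **{o: current[o].ravel() for o in OUTCOMES},
        })
        out_frames.append(done)
    return out_frames


def pool_fits(fits: list) -> pd.DataFrame:
    """Rubin-pool a list of WCLSFit objects (same terms) into one table."""
    terms = fits[0].terms
    rows = []
    for j, t in enumerate(terms):
        pooled = pool_rubin([(f.params[j], f.estimates[j].se) for f in fits])
        lo, hi = pooled.ci()
        rows.append({"term": t, "estimate": pooled.estimate, "se": pooled.se,
                     "ci_lo": lo, "ci_hi": hi, "p": pooled.p_value,
                     "df": pooled.df, "between_var": pooled.between_var})
    return pd.DataFrame(rows)
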