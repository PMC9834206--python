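"""Robustness analyses: nonlinear (spline) time-varying moderation and
alternative missing-data treatments.

The spline moderation replaces the linear ``(A - p_tilde) * week`` term with
``(A - p_tilde) * f(week)`` where ``f`` is either a natural cubic spline
(fixed df; df = 2 is exactly the linear fit) or a penalized cubic smoothing
spline whose smoothing parameter is chosen by REML, treating the penalized
coefficients as a random effect. Pointwise CIs come from the cluster-robust
sandwich with the penalized bread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import SingularDesignError
from .wcls import DEFAULT_CONTROLS, OUTCOME_COLUMN, cluster_sandwich, \
    treatment_indicator


@dataclass(frozen=True)
class SplineSpec:
    basis: str = "penalized"    # "penalized" (cubic smoothing, REML) | "natural_cubic"
    df: int = 4                 # natural-cubic dimension (2 = linear)
    n_knots: int = 6            # basis dimension for the penalized variant

    def validate(self, n_distinct: int) -> None:
        if self.basis not in ("penalized", "natural_cubic"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.df < 2:
            raise ValueError("df must be >= 2")
        size = self.df if self.basis == "natural_cubic" else self.n_knots
        if size > n_distinct:
            raise ValueError(
                f"basis dimension {size} exceeds {n_distinct} distinct week values")


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    With K knots the basis has K columns [1, x, N_1, ..., N_{K-2}]; K = 2
    (boundary knots only) is exactly the linear basis.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    cols = [np.ones_like(x), x]

    def d(j):
        return (np.clip(x - knots[j], 0, None) ** 3
                - np.clip(x - knots[-1], 0, None) ** 3) / (knots[-1] - knots[j])

    dlast = d(K - 2) if K >= 2 else None
    for j in range(K - 2):
        cols.append(d(j) - dlast)
    return np.column_stack(cols)


def _design(data: pd.DataFrame, outcome: str, p_tilde: float):
    controls = DEFAULT_CONTROLS[outcome]
    ycol = OUTCOME_COLUMN.get(outcome, outcome)
    df = data.copy()
    df["_A"] = treatment_indicator(df, outcome)
    keep = df[[ycol, *controls]].notna().all(axis=1)
    df = df[keep]
    y = df[ycol].to_numpy(float)
    Ac = df["_A"].to_numpy(float) - p_tilde
    Xc = np.column_stack([np.ones(len(df))]
                         + [df[c].to_numpy(float) for c in controls])
    week = df["week"].to_numpy(float)
    clusters = df["team_id"].to_numpy()
    return y, Ac, Xc, week, clusters


def fit_spline_moderation(data: pd.DataFrame, outcome: str,
                          spec: SplineSpec = SplineSpec(),
                          p_tilde: float = 0.5) -> pd.DataFrame:
    """Effect curve f̂(week) with pointwise 95% CIs, evaluated at each week."""
    y, Ac, Xc, week, clusters = _design(data, outcome, p_tilde)
    weeks_grid = np.sort(np.unique(week))
    spec.validate(len(weeks_grid))

    if spec.basis == "natural_cubic":
        knots = np.quantile(weeks_grid, np.linspace(0, 1, spec.df))
        B = natural_cubic_basis(week, knots)                # includes 1, x
        X = np.column_stack([Xc, Ac[:, None] * B])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("spline design is rank deficient")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        V = cluster_sandwich(X, resid, np.ones(len(y)), clusters)
        Bg = natural_cubic_basis(weeks_grid, knots)
        sl = slice(Xc.shape[1], None)
        curve = Bg @ beta[sl]
        var = np.einsum("ij,jk,ik->i", Bg, V[sl, sl], Bg)
    else:
        curve, var, weeks_grid = _penalized_curve(y, Ac, Xc, week, clusters,
                                                  spec.n_knots)

    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({"week": weeks_grid, "estimate": curve, "se": se,
                         "ci_lo": curve - 1.96 * se, "ci_hi": curve + 1.96 * se})


def _penalized_curve(y, Ac, Xc, week, clusters, n_knots):
    """Cubic smoothing-spline effect curve; lambda by REML.

    f(w) = b0 + b1 w + sum_j d_j |w - k_j|^3 with penalty d' Omega d
    (Omega_jk = |k_j - k_k|^3); the unpenalized null space (intercept and
    linear trend of the effect) lives with the controls in the fixed part.
    """
    weeks_grid = np.sort(np.unique(week))
    knots = np.quantile(weeks_grid, np.linspace(0, 1, n_knots))

    def radial(x):
        return np.abs(x[:, None] - knots[None, :]) ** 3

    omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    # reparameterize so the penalty is the identity: Z = R L^{-T}
    evals, evecs = np.linalg.eigh(omega)
    pos = evals > 1e-8 * evals.max()
    L_inv_t = evecs[:, pos] / np.sqrt(evals[pos])

    X0 = np.column_stack([Xc, Ac, Ac * week])               # fixed part
    Z = (Ac[:, None] * radial(week)) @ L_inv_t              # penalized part
    n, p0 = X0.shape
    q = Z.shape[1]

    def negative_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        # V0 = I + Z Z' / lam; use Woodbury through the q x q inner matrix
        M = lam * np.eye(q) + Z.T @ Z
        Minv = np.linalg.inv(M)

        def vinv(u):
            return u - Z @ (Minv @ (Z.T @ u))

        Vy = vinv(y)
        VX = vinv(X0)
        XtVX = X0.T @ VX
        coef = np.linalg.solve(XtVX, X0.T @ Vy)
        r = float(y @ Vy - (X0.T @ Vy) @ coef)
        logdet_v = float(np.linalg.slogdet(np.eye(q) + Z.T @ Z / lam)[1])
        logdet_x = float(np.linalg.slogdet(XtVX)[1])
        return 0.5 * ((n - p0) * np.log(max(r, 1e-300)) + logdet_v + logdet_x)

    res = optimize.minimize_scalar(negative_reml, bounds=(-10.0, 25.0),
                                   method="bounded")
    lam = float(np.exp(res.x))

    X = np.column_stack([X0, Z])
    S = np.zeros((X.shape[1], X.shape[1]))
    S[p0:, p0:] = np.eye(q)
    A = X.T @ X + lam * S
    beta = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta

    # cluster sandwich with penalized bread; Mancl-DeRouen bias-corrected
    # residuals guard against small-sample undercoverage of the band
    Ainv = np.linalg.inv(A)
    k = X.shape[1]
    meat = np.zeros((k, k))
    for c in np.unique(clusters):
        m = clusters == c
        Xg, rc = X[m], resid[m]
        Hcc = Xg @ Ainv @ Xg.T
        rc = np.linalg.solve(np.eye(len(rc)) - Hcc, rc)
        meat += np.outer(Xg.T @ rc, Xg.T @ rc)
    V = Ainv @ meat @ Ainv

    Cg = np.column_stack([np.ones(len(weeks_grid)), weeks_grid,
                          radial(weeks_grid) @ L_inv_t])
    sl = slice(Xc.shape[1], None)
    curve = Cg @ beta[sl]
    var = np.einsum("ij,jk,ik->i", Cg, V[sl, sl], Cg)
    return curve, var, weeks_grid


# ---------------------------------------------------------------------------
# alternative missing-data treatments
# ---------------------------------------------------------------------------

def last_observed_day(records: pd.DataFrame) -> pd.Series:
    """Per-intern last day_index with any observed outcome (-1 if none)."""
    obs = records[["steps", "sleep_min", "mood"]].notna().any(axis=1)
    last = records.loc[obs].groupby("intern_id")["day_index"].max()
    return last.reindex(records["intern_id"].unique(), fill_value=-1)


def complete_case_dropout(imputed: pd.DataFrame, observed: pd.DataFrame
                          ) -> pd.DataFrame:
    """Blank imputed values after each intern's last observed data point.

    ``observed`` is the pre-imputation table from which dropout is inferred.
    Idempotent: applying twice equals applying once.
    """
    last = last_observed_day(observed)
    out = imputed.copy()
    cutoff = out["intern_id"].map(last).fillna(-1)
    after = out["day_index"] > cutoff
    out.loc[after, ["steps", "sleep_min", "mood"]] = np.nan
    return out


def complete_case_weekly(team_week: pd.DataFrame, records: pd.DataFrame,
                         interns: pd.DataFrame, outcome: str,
                         max_missing_per_week: int = 5) -> pd.DataFrame:
    """Drop team-weeks with more than ``max_missing_per_week`` missing
    person-days of ``outcome`` (column name in the records table)."""
    rec = records.merge(interns.loc[interns["team_id"].notna(),
                                    ["intern_id", "team_id"]], on="intern_id")
    rec["week_index"] = rec["day_index"] // 7
    sizes = interns[interns["team_id"].notna()].groupby("team_id").size()
    obs = rec.groupby(["team_id", "week_index"])[outcome].count()
    total = 7 * sizes.reindex(obs.index.get_level_values("team_id")).to_numpy()
    missing = total - obs.to_numpy()
    bad = obs.index[missing > max_missing_per_week]
    keep = ~pd.MultiIndex.from_frame(team_week[["team_id", "week_index"]]).isin(bad)
    return team_week[keep].reset_index(drop=True)


def compare_mi_vs_cc(mi_table: pd.DataFrame, cc_table: pd.DataFrame
                     ) -> pd.DataFrame:
    """Side-by-side estimates with standardized differences.

    Inputs are term-level tables with ``term``, ``estimate`` and ``se``
    columns (e.g. from :func:`teammrt.impute.pool_fits` and
    ``WCLSFit.to_frame``).
    """
    cc = cc_table.rename(columns={"estimate": "estimate_cc", "se": "se_cc"})
    mi = mi_table.rename(columns={"estimate": "estimate_mi", "se": "se_mi"})
    merged = mi.merge(cc[["term", "estimate_cc", "se_cc"]], on="term")
    pooled_se = np.sqrt(merged["se_mi"] ** 2 + merged["se_cc"] ** 2)
    merged["std_difference"] = (merged["estimate_mi"] - merged["estimate_cc"]) / pooled_se
    return merged[["term", "estimate_mi", "se_mi", "estimate_cc", "se_cc",
                   "std_difference"]]
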