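"""Post-stratification raking weights (iterative proportional fitting).

The two-step scheme matches the enrolled sample to reference-population
margins: step 1 rakes on specialty (w1); step 2 rakes on sex and race within
each specialty group (surgical / nonsurgical), starting from the w1-weighted
sample (w2). Final weights are w1 * w2, normalized to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SURGICAL_SPECIALTIES
from .exceptions import RakingError

# Collapse the survey's finer race categories onto the three-level reference
# classification (White / Asian / underrepresented-minority-or-other).
RACE_COLLAPSE = {
    "white": "white",
    "asian": "asian",
    "black": "urm_or_other",
    "hispanic": "urm_or_other",
    "arab_middle_eastern": "urm_or_other",
    "other_multiracial": "urm_or_other",
}


# Synthetic stand-in for a national reference population of first-year
# residents (NOT real registry data): specialty mix close to a large cohort's,
# near-parity sex split, and a White/Asian/URM-or-other race mix, given
# separately for surgical and nonsurgical residents.
SYNTHETIC_REFERENCE_MARGINS: dict = {
    "specialty": {
        "internal_medicine": 0.26, "surgery": 0.15, "pediatrics": 0.10,
        "emergency_medicine": 0.09, "psychiatry": 0.06, "obgyn": 0.05,
        "anesthesiology": 0.06, "family_medicine": 0.09, "neurology": 0.03,
        "med_peds": 0.02, "transitional": 0.03, "other": 0.06,
    },
    "by_group": {
        "surgical": {
            "sex": {"female": 0.45, "male": 0.55},
            "race": {"white": 0.55, "asian": 0.22, "urm_or_other": 0.23},
        },
        "nonsurgical": {
            "sex": {"female": 0.52, "male": 0.48},
            "race": {"white": 0.50, "asian": 0.26, "urm_or_other": 0.24},
        },
    },
}


@dataclass
class WeightVector:
    weights: pd.Series          # indexed like the sample
    converged: bool
    iterations: int
    max_deviation: float


def _normalize_margin(margin: dict[str, float]) -> dict[str, float]:
    total = float(sum(margin.values()))
    if total <= 0:
        raise RakingError("margin has nonpositive total mass")
    return {k: v / total for k, v in margin.items()}


def rake(sample: pd.DataFrame, margins: dict[str, dict[str, float]],
         targets: list[str], tol: float = 1e-6, max_iter: int = 100,
         base_weights: pd.Series | None = None, normalize: bool = True
         ) -> WeightVector:
    """Iterative proportional fitting over the listed margin variables.

    ``margins[var]`` maps category -> target share (shares or counts; they
    are normalized). Iterates until the maximum relative deviation of every
    weighted margin from its target falls below ``tol``. Raises
    :class:`RakingError` when a target category has mass but no sample rows.
    With one target variable this is one-shot post-stratification
    (weight = target share / sample share).
    """
    w = (pd.Series(1.0, index=sample.index) if base_weights is None
         else base_weights.astype(float).copy())
    marg = {v: _normalize_margin(margins[v]) for v in targets}
    for v in targets:
        present = set(sample[v].unique())
        for cat, share in marg[v].items():
            if share > 0 and cat not in present:
                raise RakingError(
                    f"category {cat!r} of {v!r} has target mass {share} "
                    "but no sample rows; convergence impossible")

    def max_dev() -> float:
        dev = 0.0
        for v in targets:
            got = w.groupby(sample[v]).sum() / w.sum()
            for cat, share in marg[v].items():
                if share > 0:
                    dev = max(dev, abs(got.get(cat, 0.0) - share) / share)
        return dev

    it = 0
    deviation = max_dev()
    while deviation >= tol and it < max_iter:
        for v in targets:
            got = w.groupby(sample[v]).sum() / w.sum()
            factor = sample[v].map(
                lambda c: marg[v].get(c, 0.0) / got[c] if got.get(c, 0) > 0 else 0.0)
            w = w * factor.astype(float)
        it += 1
        deviation = max_dev()
    if normalize:
        w = w / w.mean()
    return WeightVector(w, deviation < tol, it, deviation)


def specialty_group(specialty: pd.Series) -> pd.Series:
    return specialty.map(
        lambda s: "surgical" if s in SURGICAL_SPECIALTIES else "nonsurgical")


def sample_margins(interns: pd.DataFrame) -> dict:
    """Population margins computed from a cohort itself (self-raking yields
    unit weights; useful as a synthetic reference)."""
    grp = specialty_group(interns["specialty"])
    race = interns["race"].map(RACE_COLLAPSE)
    by_group = {}
    for g in ("surgical", "nonsurgical"):
        m = grp == g
        if m.any():
            by_group[g] = {
                "sex": interns.loc[m, "sex"].value_counts(normalize=True).to_dict(),
                "race": race[m].value_counts(normalize=True).to_dict(),
            }
    return {"specialty": interns["specialty"].value_counts(normalize=True).to_dict(),
            "by_group": by_group}


def two_step_weights(sample: pd.DataFrame, margins: dict,
                     tol: float = 1e-6, max_iter: int = 100,
                     trim_percentiles: tuple[float, float] | None = None
                     ) -> pd.DataFrame:
    """w1 (specialty raking), then w2 (sex x race raking within specialty
    group on the w1-weighted sample); returns intern_id, w1, w2, w_final.

    ``margins`` needs a ``"specialty"`` margin and per-group ``"by_group"``
    sex/race margins (see :func:`sample_margins` for the layout). Optional
    trimming clips final weights at the given percentiles (off by default).
    """
    df = sample.copy()
    df["_race3"] = df["race"].map(RACE_COLLAPSE).fillna("urm_or_other")
    df["_group"] = specialty_group(df["specialty"])

    step1 = rake(df, {"specialty": margins["specialty"]}, ["specialty"],
                 tol=tol, max_iter=max_iter, normalize=True)
    w1 = step1.weights

    w2 = pd.Series(1.0, index=df.index)
    for g, gm in margins["by_group"].items():
        m = df["_group"] == g
        if not m.any():
            continue
        sub = df.loc[m].rename(columns={"_race3": "race3"})
        step2 = rake(sub, {"sex": gm["sex"], "race3": gm["race"]},
                     ["sex", "race3"], tol=tol, max_iter=max_iter,
                     base_weights=w1[m], normalize=False)
        # w2 is the multiplicative adjustment on top of w1
        w2.loc[m] = step2.weights / w1[m]

    w_final = w1 * w2
    if trim_percentiles is not None:
        lo, hi = np.percentile(w_final, trim_percentiles)
        w_final = w_final.clip(lo, hi)
    w_final = w_final / w_final.mean()

    return pd.DataFrame({"intern_id": df["intern_id"].to_numpy(),
                         "w1": w1.to_numpy(), "w2": w2.to_numpy(),
                         "w_final": w_final.to_numpy()})


def team_analysis_weights(weight_df: pd.DataFrame, interns: pd.DataFrame
                          ) -> pd.Series:
    """Team-level analysis weight = mean of member weights."""
    merged = weight_df.merge(interns[["intern_id", "team_id"]], on="intern_id")
    return merged.groupby("team_id")["w_final"].mean()
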