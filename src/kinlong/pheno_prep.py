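"""Trait preprocessing: medication imputation, per-person summaries,
covariate construction and screening.

Blood-pressure values measured on antihypertensive treatment understate
the untreated phenotype.  The imputation used here replaces each
treated person-visit value v by the mean of all strictly higher
observed values among person-visits of the same sex within +/- 10 years
of age (the subject's own visits excluded, pools always formed from
pre-imputation values); if no such observation exists the value is kept
and a warning logged.

Person-level views of the longitudinal table are the first exam
(baseline analysis) or the mean over exams of the trait and of every
time-varying covariate (mean-measure analysis).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm_core import ModelData, fit_lmm, wald_test
from .pedkin import KinshipMatrix

__all__ = [
    "impute_medicated",
    "extract_baseline",
    "mean_over_visits",
    "build_covariates",
    "screen_covariates",
    "AGE_WINDOW_YEARS",
]

logger = logging.getLogger(__name__)

AGE_WINDOW_YEARS = 10.0


def impute_medicated(
    tbl: pd.DataFrame, trait: str = "trait", return_audit: bool = False
):
    """Impute treated person-visits to their expected untreated value.

    For each row with ``medicated == 1`` and observed value v, age a and
    sex s, the reference pool is every person-visit observation (any
    subject except the one being imputed, any visit, pre-imputation
    values) with the same sex, age within the closed window
    [a - 10, a + 10], and trait value strictly greater than v.  The
    imputed value is the pool mean; an empty pool retains v with a
    logged warning.  The imputed value is therefore never below the
    observed one.
    """
    if trait not in tbl.columns:
        raise KeyError(f"trait column {trait!r} absent from phenotype table")
    if "medicated" not in tbl.columns:
        raise KeyError("phenotype table lacks a 'medicated' column")
    out = tbl.copy()
    values = tbl[trait].to_numpy(dtype=float)  # pre-imputation pool values
    ages = tbl["age"].to_numpy(dtype=float)
    sexes = tbl["sex"].to_numpy()
    ids = tbl["individual_id"].to_numpy()
    med_rows = np.flatnonzero(tbl["medicated"].to_numpy() == 1)
    audit = []
    new_values = values.copy()
    for r in med_rows:
        v, a, s = values[r], ages[r], sexes[r]
        pool = (
            (sexes == s)
            & (np.abs(ages - a) <= AGE_WINDOW_YEARS)
            & (values > v)
            & (ids != ids[r])
        )
        n_pool = int(pool.sum())
        if n_pool == 0:
            logger.warning(
                "no higher-valued %s observations for %s (sex %s, age %.1f, value %.2f); "
                "value retained",
                trait, ids[r], s, a, v,
            )
            imputed = v
        else:
            imputed = float(values[pool].mean())
        new_values[r] = imputed
        audit.append(
            {
                "individual_id": ids[r],
                "visit": tbl["visit"].iloc[r],
                "observed": v,
                "imputed": imputed,
                "pool_size": n_pool,
            }
        )
    out[trait] = new_values
    if return_audit:
        return out, pd.DataFrame(
            audit, columns=["individual_id", "visit", "observed", "imputed", "pool_size"]
        )
    return out


_TIME_VARYING = ["age", "smoke"]


def extract_baseline(tbl: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: the minimum-visit exam with its covariates."""
    idx = tbl.groupby("individual_id", sort=False)["visit"].idxmin()
    out = tbl.loc[idx].copy().reset_index(drop=True)
    out["n_visits_used"] = 1
    return out


def mean_over_visits(tbl: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: trait and time-varying covariates averaged.

    Time-invariant covariates (sex, pedigree id) are passed through;
    ``n_visits_used`` records how many exams contributed.
    """
    g = tbl.groupby("individual_id", sort=False)
    out = g.agg(
        pedigree_id=("pedigree_id", "first"),
        trait=("trait", "mean"),
        age=("age", "mean"),
        smoke=("smoke", "mean"),
        sex=("sex", "first"),
        medicated=("medicated", "max"),
        n_visits_used=("visit", "size"),
    ).reset_index()
    out["visit"] = 0
    cols = ["pedigree_id", "individual_id", "visit", "age", "sex",
            "smoke", "medicated", "trait", "n_visits_used"]
    return out[cols]


def build_covariates(tbl: pd.DataFrame, trait_kind: str) -> tuple[pd.DataFrame, list[str]]:
    """Covariate columns for an SBP-like or DBP-like analysis.

    SBP-like traits adjust for age, sex and tobacco smoking; DBP-like
    traits additionally include centered age squared, the centering mean
    taken over all rows of the supplied (analysis-ready) table.
    Returns (table with covariate columns appended, covariate names).
    """
    if trait_kind not in ("sbp_like", "dbp_like"):
        raise ValueError(f"unknown trait kind {trait_kind!r}")
    for col in ("age", "sex", "smoke"):
        if col not in tbl.columns:
            raise KeyError(f"covariate source column {col!r} missing")
    out = tbl.copy()
    out["male"] = (out["sex"].astype(int) == 1).astype(float)
    names = ["age", "male", "smoke"]
    if trait_kind == "dbp_like":
        center = out["age"].mean()
        out["age_c_sq"] = (out["age"] - center) ** 2
        names.append("age_c_sq")
    return out, names


def screen_covariates(
    tbl: pd.DataFrame,
    candidates: list[str],
    K: KinshipMatrix,
    alpha: float = 0.05,
    trait: str = "trait",
    criterion: str = "ML",
) -> list[str]:
    """Retain candidates with Wald p < alpha as sole fixed effect.

    Each candidate is tested one at a time in the kinship
    random-intercept model (intercept + candidate).
    """
    y = tbl[trait].to_numpy(dtype=float)
    person_index = K.index_of(tbl["individual_id"].tolist())
    selected = []
    for cand in candidates:
        if cand not in tbl.columns:
            raise KeyError(f"candidate column {cand!r} absent")
        x = pd.to_numeric(tbl[cand], errors="coerce").to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"candidate column {cand!r} is not numeric")
        X = np.column_stack([np.ones_like(y), x])
        fit = fit_lmm(
            ModelData(y=y, X=X, person_index=person_index, K=K,
                      xnames=["intercept", cand]),
            criterion=criterion,
        )
        _, _, p = wald_test(fit, cand)
        if p < alpha:
            selected.append(cand)
    return selected
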