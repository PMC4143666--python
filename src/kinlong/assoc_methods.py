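"""The four kinship-structured association strategies.

Given a longitudinal phenotype table, SNP dosages and a kinship matrix,
each runner tests every SNP for association with the trait under a
mixed model whose person-level random intercept has covariance
proportional to the kinship matrix:

* ``baseline``  — first exam only, person-level model (ML);
* ``lme``       — all person-visit rows, longitudinal random-intercept
  model (REML);
* ``mean``      — per-person means of trait and time-varying
  covariates (ML);
* ``twostage``  — a single no-SNP longitudinal fit yields per-person
  predicted random intercepts (BLUPs), which are then regressed on each
  SNP with their own kinship-structured random effect (ML, both
  stages).  The first stage is SNP-independent, making this the fastest
  per-SNP strategy.

``mode="exact"`` refits the variance components per SNP; ``mode="fast"``
freezes the variance ratio at the no-SNP null fit and tests each SNP by
weighted least squares in the rotated coordinates (GRAMMAR/EMMAX
style), which is the choice for genome-scale null-calibration runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pheno_prep
from .lmm_core import ModelData, Rotation, SnpScanner, fit_lmm, wald_test
from .pedkin import KinshipMatrix
from .simdata import GenotypeDosages

__all__ = ["run_baseline", "run_lme", "run_mean", "run_twostage", "run_all", "METHODS"]

METHODS = ("baseline", "lme", "mean", "twostage")

_RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "method", "effect", "se", "p",
    "n_individuals", "n_observations", "monomorphic",
]


def _check_alignment(pheno: pd.DataFrame, geno: GenotypeDosages, K: KinshipMatrix) -> None:
    people = set(pheno["individual_id"])
    missing_k = sorted(people - set(K.ids))
    missing_g = sorted(people - set(geno.ids))
    if missing_k or missing_g:
        raise ValueError(
            "phenotyped individuals absent from "
            + "; ".join(
                f"{src}: {ids}" for src, ids in
                [("kinship matrix", missing_k), ("genotypes", missing_g)] if ids
            )
        )


def _drop_missing_trait(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    ok = np.isfinite(pheno[trait].to_numpy(dtype=float))
    if not ok.all():
        import logging

        logging.getLogger(__name__).info(
            "dropping %d person-visit rows with missing %s", int((~ok).sum()), trait
        )
    return pheno[ok]


def _model_pieces(pheno, covar_names, K, trait="trait"):
    y = pheno[trait].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(pheno))] + [pheno[c].to_numpy(dtype=float) for c in covar_names]
    )
    xnames = ["intercept"] + list(covar_names)
    person_index = K.index_of(pheno["individual_id"].tolist())
    return y, X, xnames, person_index


def _snp_scan(
    pheno, covar_names, geno, K, method, criterion, mode, trait="trait"
) -> pd.DataFrame:
    """Shared per-SNP engine for all four runners (stage 2 included)."""
    pheno = _drop_missing_trait(pheno, trait)
    _check_alignment(pheno, geno, K)
    y, X, xnames, person_index = _model_pieces(pheno, covar_names, K, trait)
    geno_pos = {iid: i for i, iid in enumerate(geno.ids)}
    row_geno = np.array([geno_pos[i] for i in pheno["individual_id"]], dtype=np.intp)
    n_ind = pheno["individual_id"].nunique()
    n_obs = len(pheno)
    rot = Rotation(K, person_index)
    records = []
    if mode == "fast":
        scanner = SnpScanner(
            ModelData(y=y, X=X, person_index=person_index, K=K, xnames=xnames),
            criterion=criterion, rotation=rot,
        )
        eff, se, p, mono = scanner.scan(geno.dosages[row_geno, :])
        for j, snp in enumerate(geno.snp_ids):
            records.append(
                (snp, geno.chroms[j], int(geno.positions[j]), method,
                 float(eff[j]), float(se[j]), float(p[j]), n_ind, n_obs, bool(mono[j]))
            )
    elif mode == "exact":
        for j, snp in enumerate(geno.snp_ids):
            g_obs = geno.dosages[row_geno, j]
            if np.ptp(g_obs) <= 0.0:
                records.append(
                    (snp, geno.chroms[j], int(geno.positions[j]), method,
                     0.0, np.inf, 1.0, n_ind, n_obs, True)
                )
                continue
            fit = fit_lmm(
                ModelData(
                    y=y, X=np.column_stack([X, g_obs]), person_index=person_index,
                    K=K, xnames=xnames + ["snp"],
                ),
                criterion=criterion, rotation=rot,
            )
            est, se_j, p_j = wald_test(fit, "snp")
            records.append(
                (snp, geno.chroms[j], int(geno.positions[j]), method,
                 est, se_j, p_j, n_ind, n_obs, False)
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(records, columns=_RESULT_COLUMNS)


def run_baseline(
    pheno: pd.DataFrame, geno: GenotypeDosages, K: KinshipMatrix,
    covar_names: list[str], criterion: str = "ML", mode: str = "exact",
) -> pd.DataFrame:
    """Baseline (first-exam) association: person-level ML fit per SNP."""
    return _snp_scan(pheno, covar_names, geno, K, "baseline", criterion, mode)


def run_mean(
    pheno: pd.DataFrame, geno: GenotypeDosages, K: KinshipMatrix,
    covar_names: list[str], criterion: str = "ML", mode: str = "exact",
) -> pd.DataFrame:
    """Mean-measure association on per-person visit means (ML)."""
    return _snp_scan(pheno, covar_names, geno, K, "mean", criterion, mode)


def run_lme(
    pheno: pd.DataFrame, geno: GenotypeDosages, K: KinshipMatrix,
    covar_names: list[str], criterion: str = "REML", mode: str = "exact",
) -> pd.DataFrame:
    """Longitudinal mixed-effects association on all person-visit rows (REML)."""
    return _snp_scan(pheno, covar_names, geno, K, "lme", criterion, mode)


def run_twostage(
    pheno: pd.DataFrame, geno: GenotypeDosages, K: KinshipMatrix,
    covar_names: list[str], criterion: str = "ML", mode: str = "exact",
) -> pd.DataFrame:
    """Two-stage association: BLUPs from a no-SNP longitudinal fit, then a
    per-SNP kinship-structured regression of the BLUPs on dosage.

    Stage 2 contains only an intercept and the SNP (covariate adjustment
    enters through stage 1).
    """
    pheno = _drop_missing_trait(pheno, "trait")
    _check_alignment(pheno, geno, K)
    y, X, xnames, person_index = _model_pieces(pheno, covar_names, K)
    stage1 = fit_lmm(
        ModelData(y=y, X=X, person_index=person_index, K=K, xnames=xnames),
        criterion=criterion,
    )
    if not stage1.converged:
        raise RuntimeError(
            "stage-1 longitudinal fit did not converge "
            f"(boundary={stage1.boundary}); two-stage analysis aborted"
        )
    observed = [i for i in K.ids if i in set(pheno["individual_id"])]
    if stage1.vc.var_kin <= 0.0:
        # full shrinkage: every BLUP is zero and no SNP can be informative
        records = [
            (snp, geno.chroms[j], int(geno.positions[j]), "twostage",
             0.0, np.inf, 1.0, len(observed), len(observed), True)
            for j, snp in enumerate(geno.snp_ids)
        ]
        return pd.DataFrame(records, columns=_RESULT_COLUMNS)
    stage2_pheno = pd.DataFrame(
        {"individual_id": observed, "trait": stage1.blups[K.index_of(observed)]}
    )
    return _snp_scan(stage2_pheno, [], geno, K, "twostage", "ML", mode)


def run_all(
    pheno_long: pd.DataFrame,
    geno: GenotypeDosages,
    K: KinshipMatrix,
    trait_kind: str = "sbp_like",
    criterion: str = "method-default",
    mode: str = "exact",
    impute: bool = True,
) -> pd.DataFrame:
    """Apply trait preprocessing then all four association strategies.

    ``criterion="method-default"`` uses REML for the longitudinal
    mixed-effects model and ML everywhere else; passing ``"ml"`` or
    ``"reml"`` forces one criterion for every method.
    """
    _check_alignment(pheno_long, geno, K)
    tbl = pheno_prep.impute_medicated(pheno_long) if impute else pheno_long

    def crit(default):
        return default if criterion == "method-default" else criterion.upper()

    views = {
        "baseline": pheno_prep.extract_baseline(tbl),
        "mean": pheno_prep.mean_over_visits(tbl),
        "lme": tbl,
        "twostage": tbl,
    }
    runners = {
        "baseline": (run_baseline, crit("ML")),
        "mean": (run_mean, crit("ML")),
        "lme": (run_lme, crit("REML")),
        "twostage": (run_twostage, crit("ML")),
    }
    out = []
    for method in METHODS:
        view, names = pheno_prep.build_covariates(views[method], trait_kind)
        runner, criterion_m = runners[method]
        out.append(runner(view, geno, K, names, criterion=criterion_m, mode=mode))
    return pd.concat(out, ignore_index=True)
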