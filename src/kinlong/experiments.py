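"""Reproducible simulation experiments: null calibration, power
comparison and parameter recovery under the package's study conditions.

The default conditions are the ones the rest of the package is
validated against: sibship-quad pedigrees, four visits five years
apart, variance components polygenic 0.5 / person 0.5 / occasion 2.0,
common SNPs, and a causal effect of 0.38 trait units per dosage at
MAF 0.3 tested against the multiple-testing threshold 0.05 / 25,676.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc_methods, evaluation, pheno_prep
from .lmm_core import ModelData, fit_lmm
from .pedkin import kinship_matrix
from .simdata import SimConfig, simulate_dataset

__all__ = [
    "null_calibration",
    "power_comparison",
    "mean_measure_recovery",
    "N_INDEPENDENT_SNPS",
]

# approximate count of LD-independent common SNPs on chromosome 3 used
# for the Bonferroni threshold in the power experiments
N_INDEPENDENT_SNPS = 25_676


def null_calibration(
    seed: int,
    n_snps: int = 20_000,
    n_pedigrees: int = 125,
    methods=assoc_methods.METHODS,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Type-I error and genomic-control lambda on a no-effect simulation.

    Each replicate simulates ``n_pedigrees`` sibship-quad pedigrees (all
    members phenotyped, 4 visits), gene-drops ``n_snps`` independent
    SNPs with MAF uniform on [0.05, 0.5] and runs each method in fast
    mode (variance components frozen at the null fit).  With
    ``n_replicates > 1`` the lambda estimate pools the p-values of all
    replicates and the type-I error is the across-replicate mean; a
    single 20,000-SNP dataset gives lambda only to about +/- 0.017
    (median sampling noise), so replication is how a calibration level
    can be resolved below that.
    """
    pvals: dict[str, list] = {m: [] for m in methods}
    type_i: dict[str, list] = {m: [] for m in methods}
    for rep in range(n_replicates):
        rep_seed = (seed * 613 + rep) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        cfg = SimConfig(
            n_pedigrees=n_pedigrees,
            pedigree_template="sibship(4)",
            mafs=tuple(rng.uniform(0.05, 0.5, size=n_snps)),
            beta_snp=0.0,
            seed=rep_seed,
        )
        _, K, geno, pheno, _ = simulate_dataset(cfg, n_snps=n_snps)
        res = assoc_methods.run_all(
            pheno, geno, K, trait_kind="sbp_like", mode="fast", impute=False
        )
        for method in methods:
            p = res.loc[res["method"] == method, "p"].to_numpy()
            pvals[method].append(p)
            type_i[method].append(float((p < 0.05).mean()))
    rows = []
    for method in methods:
        pooled = np.concatenate(pvals[method])
        rows.append(
            {
                "method": method,
                "n_snps": n_snps,
                "n_replicates": n_replicates,
                "lambda_gc": evaluation.genomic_lambda(pooled),
                "type_i_at_0.05": float(np.mean(type_i[method])),
            }
        )
    return pd.DataFrame(rows)


def power_comparison(
    seed: int,
    n_replicates: int = 200,
    n_pedigrees: int = 200,
    maf: float = 0.3,
    beta_snp: float = 0.38,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Power of the four methods at the Bonferroni threshold.

    Each replicate simulates sibship-quad pedigrees (phenotypes on the
    offspring only; parents contribute pedigree structure and gene
    dropping), one causal SNP, 4 visits, and records whether each
    method's causal-SNP p-value beats the threshold.  Returns the
    per-method power table and the minimum power advantage (percentage
    points) of the longitudinal methods over the baseline method.
    """
    if threshold is None:
        threshold = evaluation.bonferroni_threshold(N_INDEPENDENT_SNPS)
    summaries = []
    for rep in range(n_replicates):
        cfg = SimConfig(
            n_pedigrees=n_pedigrees,
            pedigree_template="sibship(4)",
            mafs=(maf,),
            beta_snp=beta_snp,
            seed=(seed * 1009 + rep) % (2**31 - 1),
        )
        ped, K, geno, pheno, truth = simulate_dataset(cfg, n_snps=1)
        offspring = set(ped.df.loc[ped.df["father"].notna(), "iid"])
        pheno = pheno[pheno["individual_id"].isin(offspring)]
        res = assoc_methods.run_all(
            pheno, geno, K, trait_kind="sbp_like", mode="exact", impute=False
        )
        for method in assoc_methods.METHODS:
            p = float(res.loc[res["method"] == method, "p"].iloc[0])
            summaries.append(
                {
                    "replicate_id": rep,
                    "method": method,
                    "causal_snp_id": truth.causal_snp_id,
                    "p_at_causal": p,
                    "significant": p < threshold,
                }
            )
    power = evaluation.estimate_power(pd.DataFrame(summaries))
    by = power.set_index("method")["power"]
    min_gain_pp = 100.0 * min(
        by[m] - by["baseline"] for m in ("lme", "mean", "twostage")
    )
    return power, float(min_gain_pp)


def mean_measure_recovery(
    seed: int,
    n_datasets: int = 200,
    n_pedigrees: int = 125,
    beta_snp: float = 0.38,
    maf: float = 0.3,
) -> dict:
    """Parameter recovery of the mean-measure model over simulated datasets.

    Averaging the 4 visits makes the person-level two-component model
    correctly specified: kinship variance = polygenic variance and
    residual variance = person variance + occasion variance / 4.
    Returns median estimates alongside those implied truths.
    """
    vks, vrs, betas = [], [], []
    truth_vc = None
    for rep in range(n_datasets):
        cfg = SimConfig(
            n_pedigrees=n_pedigrees,
            pedigree_template="sibship(4)",
            mafs=(maf,),
            beta_snp=beta_snp,
            seed=(seed * 2003 + rep) % (2**31 - 1),
        )
        _, K, geno, pheno, truth = simulate_dataset(cfg, n_snps=1)
        truth_vc = truth.implied_person_level_components(cfg.n_visits)
        mm, names = pheno_prep.build_covariates(
            pheno_prep.mean_over_visits(pheno), "sbp_like"
        )
        gpos = {i: j for j, i in enumerate(geno.ids)}
        g = geno.dosages[[gpos[i] for i in mm["individual_id"]], 0]
        X = np.column_stack(
            [np.ones(len(mm))] + [mm[c].to_numpy(dtype=float) for c in names] + [g]
        )
        fit = fit_lmm(
            ModelData(
                y=mm["trait"].to_numpy(),
                X=X,
                person_index=K.index_of(mm["individual_id"].tolist()),
                K=K,
                xnames=["intercept"] + names + ["snp"],
            ),
            criterion="ML",
        )
        vks.append(fit.vc.var_kin)
        vrs.append(fit.vc.var_resid)
        betas.append(fit.coef("snp")[0])
    return {
        "median_var_kin": float(np.median(vks)),
        "median_var_resid": float(np.median(vrs)),
        "median_beta_snp": float(np.median(betas)),
        "truth_var_kin": truth_vc[0],
        "truth_var_resid": truth_vc[1],
        "truth_beta_snp": beta_snp,
        "n_datasets": n_datasets,
    }
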