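"""Multiple-testing machinery, genomic control, power estimation and
top-hit reporting for per-SNP association results."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeDosages

__all__ = [
    "maf_filter",
    "ld_prune",
    "bonferroni_threshold",
    "genomic_lambda",
    "estimate_power",
    "top_hits",
    "manhattan_export",
    "CHI2_NULL_MEDIAN",
]

logger = logging.getLogger(__name__)

# median of the chi-square distribution with 1 degree of freedom,
# computed with the same tail function used on the p-values so that a
# constant p = 0.5 maps to lambda = 1 exactly
CHI2_NULL_MEDIAN = float(stats.chi2.isf(0.5, df=1))


def maf_filter(geno: GenotypeDosages, min_maf: float = 0.05) -> GenotypeDosages:
    """Keep common variants: estimated MAF >= min_maf (inclusive).

    The allele frequency is estimated as mean dosage / 2 and folded to
    the minor allele.
    """
    return geno.subset_snps(geno.maf() >= min_maf)


def ld_prune(
    geno: GenotypeDosages, r2_threshold: float = 0.2, window: int = 50
) -> list[str]:
    """Greedy LD pruning in position order.

    A SNP is kept iff its squared dosage correlation with every
    previously kept SNP within ``window`` positions of the scan (same
    chromosome) is below ``r2_threshold``.  Zero-variance SNPs are
    skipped with a warning.  Returns the kept snp_ids.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    D = geno.dosages
    sd = D.std(axis=0)
    centered = D - D.mean(axis=0)
    kept: list[int] = []
    for j in range(geno.n_snps):
        if sd[j] == 0.0:
            logger.warning("LD pruning skipped zero-variance SNP %s", geno.snp_ids[j])
            continue
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            if geno.chroms[k] != geno.chroms[j] or sd[k] == 0.0:
                continue
            r = float(centered[:, j] @ centered[:, k]) / (len(D) * sd[j] * sd[k])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return [geno.snp_ids[j] for j in kept]


def bonferroni_threshold(n_independent: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha / (number of independent SNPs)."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return alpha / n_independent


def genomic_lambda(pvalues) -> float:
    """Genomic-control inflation factor.

    ``lambda = median(chi2_1 quantile at 1 - p) / 0.4549...``; values
    near 1 indicate calibrated tests, above 1 inflation of type I
    error.  NaN p-values are excluded with a logged count.
    """
    p = np.asarray(pvalues, dtype=float)
    nan = np.isnan(p)
    if nan.any():
        logger.info("genomic_lambda: excluding %d NaN p-values", int(nan.sum()))
        p = p[~nan]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / CHI2_NULL_MEDIAN)


def estimate_power(summaries: pd.DataFrame) -> pd.DataFrame:
    """Power per method: fraction of significant replicates, Wilson 95% CI.

    ``summaries`` needs columns method, replicate_id, significant (or
    p_at_causal plus a threshold column from which significance was
    derived upstream).
    """
    from statsmodels.stats.proportion import proportion_confint

    if "significant" not in summaries.columns:
        raise KeyError("replicate summaries lack a 'significant' column")
    rows = []
    for method, grp in summaries.groupby("method", sort=False):
        k = int(grp["significant"].sum())
        n = len(grp)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {"method": method, "n_replicates": n, "n_significant": k,
             "power": k / n, "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(rows)


def top_hits(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Per method, the k smallest p-values sorted ascending.

    Ties break by |effect| descending, then snp_id ascending.
    """
    out = []
    for method, grp in results.groupby("method", sort=False):
        g = grp.assign(_abseff=grp["effect"].abs())
        g = g.sort_values(
            ["p", "_abseff", "snp_id"], ascending=[True, False, True], kind="mergesort"
        ).head(k)
        out.append(g.drop(columns="_abseff"))
    return pd.concat(out, ignore_index=True)


def manhattan_export(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, -log10 p, method (one row per SNP x method).

    Exact zeros (possible only from underflow upstream) are clamped to
    the smallest positive float with a logged count.
    """
    p = results["p"].to_numpy(dtype=float).copy()
    zero = p == 0.0
    if zero.any():
        logger.warning("manhattan_export: clamping %d zero p-values", int(zero.sum()))
        p[zero] = np.finfo(float).tiny
    return pd.DataFrame(
        {
            "chrom": results["chrom"].to_numpy(),
            "pos": results["pos"].to_numpy(),
            "neg_log10_p": -np.log10(p),
            "method": results["method"].to_numpy(),
            "snp_id": results["snp_id"].to_numpy(),
        }
    )
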