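"""Synthetic pedigree, genotype and longitudinal phenotype generation.

Emulates the structure of an extended-family blood-pressure study:
~20 pedigrees, up to 4 exams per person at a fixed gap, SBP/DBP-like
traits decomposed into a polygenic effect (covariance proportional to
the kinship matrix), an i.i.d. person-level effect, and occasion-level
noise, with common-variant SNP dosages produced by gene dropping and an
optional antihypertensive-medication masking step.

The generative model per person-visit is

    y_ijt = b0 + b' x_ijt + bs * SNP_ij + g_ij + a_ij + e_ijt

with g ~ N(0, var_polygenic * Sigma_kin) per pedigree block,
a ~ N(0, var_person) i.i.d. per person and e ~ N(0, var_occasion)
i.i.d. per visit.  Covariates are age (advancing by the visit gap),
sex and tobacco smoking.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedkin import KinshipMatrix, PedigreeTable

__all__ = [
    "SimConfig",
    "GenotypeDosages",
    "TruthRecord",
    "build_pedigrees",
    "gene_drop",
    "drop_founder_alleles",
    "mc_kinship",
    "simulate_polygenic",
    "simulate_longitudinal",
    "apply_medication",
    "simulate_dataset",
    "with_ld_twins",
    "write_pheno_tsv",
    "read_pheno_tsv",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults give a blood-pressure-like quantitative trait on extended
    pedigrees: polygenic, person and occasion variances of 0.5 / 0.5 /
    2.0 trait units squared, four visits five years apart, and common
    SNPs (MAF in [0.05, 0.5]).
    """

    n_pedigrees: int = 20
    pedigree_template: str = "three_generation"
    mafs: tuple[float, ...] = (0.3,)
    beta_snp: float = 0.0
    beta_covars: dict = field(
        default_factory=lambda: {"intercept": 120.0, "age": 0.4, "male": 3.0, "smoke": 2.0}
    )
    var_polygenic: float = 0.5
    var_person: float = 0.5
    var_occasion: float = 2.0
    n_visits: int = 4
    visit_gap_years: float = 5.0
    dropout_rate: float = 0.0
    medication_model: str = "none"          # "none" | "threshold"
    medication_threshold: float = float("inf")
    treatment_effect: float = 10.0
    causal_snp: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_polygenic", "var_person", "var_occasion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.n_visits <= 4:
            raise ValueError("n_visits must be in 1..4")
        for f in self.mafs:
            if not 0.05 <= f <= 0.5:
                raise ValueError(f"MAF {f} outside the common-variant range [0.05, 0.5]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class GenotypeDosages:
    """Per-SNP dosages (expected minor-allele counts) for a set of individuals."""

    ids: list[str]
    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray
    dosages: np.ndarray  # individuals x SNPs, values in [0, 2]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match ids x snp_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for c in set(self.chroms):
            pos_c = self.positions[[i for i, cc in enumerate(self.chroms) if cc == c]]
            if np.any(np.diff(pos_c) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDosages":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDosages(
            ids=self.ids,
            snp_ids=[self.snp_ids[i] for i in keep],
            chroms=[self.chroms[i] for i in keep],
            positions=self.positions[keep],
            dosages=self.dosages[:, keep],
        )


@dataclass
class TruthRecord:
    """Generative ground truth kept alongside a simulated dataset."""

    causal_snp_id: str | None
    beta_snp: float
    var_polygenic: float
    var_person: float
    var_occasion: float
    polygenic: dict[str, float]
    person_effect: dict[str, float]
    latent_trait: dict | None = None  # (individual_id, visit) -> pre-medication value

    def implied_person_level_components(self, n_visits: int) -> tuple[float, float]:
        """(kinship, residual) variance of per-person visit means.

        Averaging over v visits leaves the polygenic component intact
        and shrinks only the occasion noise: residual variance is
        var_person + var_occasion / v.
        """
        return self.var_polygenic, self.var_person + self.var_occasion / n_visits

    def to_json(self, path) -> None:
        d = asdict(self)
        if d["latent_trait"] is not None:
            d["latent_trait"] = {f"{k[0]}|{k[1]}": v for k, v in d["latent_trait"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


_TEMPLATE_RE = re.compile(r"^(sibship|nuclear)\((\d+)\)$|^three_generation$")


def _template_members(template: str):
    """Yield (iid_suffix, father_suffix, mother_suffix, sex_code) per member."""
    m = _TEMPLATE_RE.match(template)
    if not m:
        raise ValueError(f"unknown pedigree template {template!r}")
    if template == "three_generation":
        # 2 grandparents, 3 of their children married to 3 founder
        # spouses, 2 grandchildren per couple: 14 members
        members = [
            ("gp1", None, None, 1),
            ("gp2", None, None, 2),
        ]
        for c in range(1, 4):
            csex = 1 if c % 2 else 2
            members.append((f"c{c}", "gp1", "gp2", csex))
            members.append((f"s{c}", None, None, 2 if csex == 1 else 1))
            fa, mo = (f"c{c}", f"s{c}") if csex == 1 else (f"s{c}", f"c{c}")
            for g in range(1, 3):
                members.append((f"g{c}{g}", fa, mo, 1 if g % 2 else 2))
        return members
    k = int(m.group(2))
    if k < 1:
        raise ValueError("sibship size must be >= 1")
    members = [("fa", None, None, 1), ("mo", None, None, 2)]
    members += [(f"o{j}", "fa", "mo", 1 if j % 2 else 2) for j in range(1, k + 1)]
    return members


def build_pedigrees(config: SimConfig) -> PedigreeTable:
    """Replicate the configured template into globally-unique pedigrees."""
    members = _template_members(config.pedigree_template)
    sex_label = {1: "male", 2: "female"}
    rows = []
    width = max(3, len(str(config.n_pedigrees)))
    for p in range(1, config.n_pedigrees + 1):
        fid = f"P{p:0{width}d}"
        for suffix, fa, mo, sex in members:
            rows.append(
                {
                    "fid": fid,
                    "iid": f"{fid}_{suffix}",
                    "father": f"{fid}_{fa}" if fa else None,
                    "mother": f"{fid}_{mo}" if mo else None,
                    "sex": sex_label[sex],
                }
            )
    return PedigreeTable(pd.DataFrame(rows))


def _drop_alleles(ped: PedigreeTable, rng: np.random.Generator, founder_draw):
    """Transmit founder alleles down the pedigree; returns (a1, a2) arrays.

    ``founder_draw(n_founders)`` supplies the two founder allele arrays.
    Children inherit one uniformly random allele from each parent.
    """
    df = ped.df
    order = ped.topological_order()
    index_of = {(f, i): k for k, (f, i) in enumerate(zip(df["fid"], df["iid"]))}
    founder_rows = [k for k in order if df["father"].iloc[k] is None and df["mother"].iloc[k] is None]
    fa1, fa2 = founder_draw(len(founder_rows))
    shape = fa1.shape[1:]
    n = len(df)
    a1 = np.empty((n,) + shape, dtype=fa1.dtype)
    a2 = np.empty((n,) + shape, dtype=fa1.dtype)
    for j, k in enumerate(founder_rows):
        a1[k], a2[k] = fa1[j], fa2[j]
    for k in order:
        row = df.iloc[k]
        if row["father"] is None and row["mother"] is None:
            continue
        f = index_of[(row["fid"], row["father"])]
        mth = index_of[(row["fid"], row["mother"])]
        pick_f = rng.integers(0, 2, size=shape)
        pick_m = rng.integers(0, 2, size=shape)
        a1[k] = np.where(pick_f == 0, a1[f], a2[f])
        a2[k] = np.where(pick_m == 0, a1[mth], a2[mth])
    return a1, a2


def gene_drop(
    ped: PedigreeTable,
    maf,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-drop one or more SNPs; returns dosages (individuals x SNPs).

    Founders draw two alleles Bernoulli(maf); every non-founder
    inherits one uniformly random allele from each parent, so genotypes
    are Mendelian-consistent by construction.  ``maf`` may be a scalar
    or a vector (one frequency per SNP).
    """
    maf_arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((maf_arr < 0) | (maf_arr > 1)):
        raise ValueError("maf must lie in [0, 1]")
    m = maf_arr.shape[0]

    def founder_draw(nf):
        u1 = rng.random((nf, m)) < maf_arr
        u2 = rng.random((nf, m)) < maf_arr
        return u1.astype(np.int8), u2.astype(np.int8)

    a1, a2 = _drop_alleles(ped, rng, founder_draw)
    dosages = (a1 + a2).astype(float)
    return dosages if np.ndim(maf) else dosages[:, 0] if m == 1 and np.isscalar(maf) else dosages


def drop_founder_alleles(
    ped: PedigreeTable, rng: np.random.Generator, n_rep: int
) -> tuple[np.ndarray, np.ndarray]:
    """Drop uniquely-labelled founder alleles ``n_rep`` independent times.

    Returns integer allele-origin labels (individuals x n_rep) for each
    of the two gametes; equality of labels means identity by descent.
    """

    def founder_draw(nf):
        base = 2 * np.arange(nf, dtype=np.int32)[:, None]
        return (
            np.broadcast_to(base, (nf, n_rep)).copy(),
            np.broadcast_to(base + 1, (nf, n_rep)).copy(),
        )

    return _drop_alleles(ped, rng, founder_draw)


def mc_kinship(
    ped: PedigreeTable, n_rep: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Monte-Carlo kinship estimate by gene dropping.

    For each pair (j, k), the kinship coefficient is estimated as the
    average probability that a random allele of j is identical by
    descent to a random allele of k.  Returns (phi_hat, mc_se, ids) in
    the input row order of ``ped``; this estimator is independent of the
    recursive computation in :mod:`kinlong.pedkin` and serves as its
    oracle.
    """
    a1, a2 = drop_founder_alleles(ped, rng, n_rep)
    n = a1.shape[0]
    phi_hat = np.zeros((n, n))
    mc_se = np.zeros((n, n))
    for j in range(n):
        for k in range(j, n):
            ibd = 0.25 * (
                (a1[j] == a1[k]).astype(float)
                + (a1[j] == a2[k])
                + (a2[j] == a1[k])
                + (a2[j] == a2[k])
            )
            est = float(ibd.mean())
            se = float(ibd.std(ddof=1) / np.sqrt(n_rep))
            phi_hat[j, k] = phi_hat[k, j] = est
            mc_se[j, k] = mc_se[k, j] = se
    return phi_hat, mc_se, ped.df["iid"].tolist()


def simulate_polygenic(
    K: KinshipMatrix, var_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one multivariate-normal polygenic vector with covariance var_g * K."""
    if var_g < 0:
        raise ValueError("var_g must be >= 0")
    out = np.zeros(K.n)
    if var_g == 0.0:
        return out
    for fid, sl in K.blocks.items():
        block = K.values[sl, sl]
        lam, U = np.linalg.eigh(block)
        if lam.min() < -1e-8 * max(lam.max(), 1.0):
            raise ValueError(f"kinship block {fid!r} is not positive semidefinite")
        lam = np.clip(lam, 0.0, None)
        z = rng.standard_normal(block.shape[0])
        out[sl] = U @ (np.sqrt(var_g * lam) * z)
    return out


def _baseline_ages(ped: PedigreeTable, rng: np.random.Generator) -> np.ndarray:
    """Age at first exam: founders'/ancestors' generation depth sets the mean."""
    df = ped.df
    depth = np.zeros(len(df), dtype=int)
    index_of = {(f, i): k for k, (f, i) in enumerate(zip(df["fid"], df["iid"]))}
    for k in ped.topological_order():
        row = df.iloc[k]
        parents = [index_of[(row["fid"], p)] for p in (row["father"], row["mother"]) if p]
        if parents:
            depth[k] = 1 + max(depth[p] for p in parents)
    return 65.0 - 25.0 * depth + rng.uniform(-5.0, 5.0, size=len(df))


def simulate_longitudinal(
    ped: PedigreeTable,
    dosages: GenotypeDosages,
    config: SimConfig,
    rng: np.random.Generator,
    K: KinshipMatrix | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the person-visit phenotype table and its ground truth.

    The causal SNP (``config.causal_snp``) contributes
    ``beta_snp * dosage``; with ``causal_snp=None`` the trait carries no
    SNP effect (the null configuration).  Ages advance by
    ``visit_gap_years``; smoking is a person-level habit with a 10%
    chance of quitting at each later exam; optional
    missing-completely-at-random dropout truncates follow-up.
    """
    from .pedkin import kinship_matrix

    if K is None:
        K = kinship_matrix(ped)
    df = ped.df
    n = len(df)
    kin_pos = K.index_of(df["iid"].tolist())

    g = simulate_polygenic(K, config.var_polygenic, rng)[kin_pos]
    a = rng.standard_normal(n) * np.sqrt(config.var_person)
    age0 = _baseline_ages(ped, rng)
    sex_code = np.where(df["sex"].to_numpy() == "male", 1, 2)
    smoke0 = (rng.random(n) < 0.2).astype(int)

    snp_effect = np.zeros(n)
    if config.causal_snp is not None:
        if config.causal_snp not in dosages.snp_ids:
            raise ValueError(f"causal SNP {config.causal_snp!r} not among simulated SNPs")
        col = dosages.snp_ids.index(config.causal_snp)
        pos = {iid: i for i, iid in enumerate(dosages.ids)}
        snp_effect = config.beta_snp * dosages.dosages[
            [pos[i] for i in df["iid"]], col
        ]

    b = config.beta_covars
    n_visits_per = np.full(n, config.n_visits)
    if config.dropout_rate > 0.0:
        # once a person misses an exam they do not return (MCAR)
        for v in range(1, config.n_visits):
            drop = rng.random(n) < config.dropout_rate
            n_visits_per = np.where(drop & (n_visits_per > v), v, n_visits_per)

    rows = []
    smoke = smoke0.copy()
    for v in range(config.n_visits):
        age_v = age0 + v * config.visit_gap_years
        if v > 0:
            quit = (rng.random(n) < 0.1) & (smoke == 1)
            smoke = np.where(quit, 0, smoke)
        e = rng.standard_normal(n) * np.sqrt(config.var_occasion)
        y = (
            b["intercept"]
            + b["age"] * age_v
            + b["male"] * (sex_code == 1)
            + b["smoke"] * smoke
            + snp_effect
            + g
            + a
            + e
        )
        for i in range(n):
            if v < n_visits_per[i]:
                rows.append(
                    (
                        df["fid"].iloc[i],
                        df["iid"].iloc[i],
                        v + 1,
                        age_v[i],
                        int(sex_code[i]),
                        int(smoke[i]),
                        0,
                        float(y[i]),
                    )
                )
    tbl = pd.DataFrame(
        rows,
        columns=[
            "pedigree_id",
            "individual_id",
            "visit",
            "age",
            "sex",
            "smoke",
            "medicated",
            "trait",
        ],
    )
    truth = TruthRecord(
        causal_snp_id=config.causal_snp,
        beta_snp=config.beta_snp if config.causal_snp is not None else 0.0,
        var_polygenic=config.var_polygenic,
        var_person=config.var_person,
        var_occasion=config.var_occasion,
        polygenic=dict(zip(df["iid"], map(float, g))),
        person_effect=dict(zip(df["iid"], map(float, a))),
    )
    return tbl, truth


def apply_medication(
    tbl: pd.DataFrame,
    threshold: float,
    treatment_effect: float,
    rng: np.random.Generator | None = None,
    truth: TruthRecord | None = None,
) -> pd.DataFrame:
    """Flag and mask visits whose latent trait exceeds ``threshold``.

    Flagged person-visits have the observed trait reduced by
    ``treatment_effect`` (a subtractive treatment model); the latent
    values are retained in ``truth.latent_trait`` when a TruthRecord is
    supplied.  ``rng`` is accepted for signature symmetry with the other
    generators (the threshold model is deterministic given the traits).
    """
    out = tbl.copy()
    latent = out["trait"].to_numpy().copy()
    flag = latent > threshold
    out["medicated"] = flag.astype(int)
    out.loc[flag, "trait"] = latent[flag] - treatment_effect
    if truth is not None:
        truth.latent_trait = {
            (r.individual_id, int(r.visit)): float(v)
            for r, v in zip(tbl.itertuples(index=False), latent)
        }
    return out


def simulate_dataset(config: SimConfig, n_snps: int | None = None):
    """End-to-end generation: pedigree, kinship, dosages, phenotypes, truth.

    Returns (ped, K, geno, pheno, truth).  SNP frequencies cycle through
    ``config.mafs`` when ``n_snps`` exceeds their count; SNP ids follow
    the ``chrom_pos`` convention on a synthetic chromosome 3 map.
    """
    from .pedkin import kinship_matrix

    rng = np.random.default_rng(config.seed)
    ped = build_pedigrees(config)
    K = kinship_matrix(ped)
    m = n_snps if n_snps is not None else len(config.mafs)
    mafs = np.resize(np.asarray(config.mafs, dtype=float), m)
    dos = gene_drop(ped, mafs, rng)
    positions = 1_000_000 + 10_000 * np.arange(m, dtype=np.int64)
    snp_ids = [f"3_{p}" for p in positions]
    geno = GenotypeDosages(
        ids=ped.df["iid"].tolist(),
        snp_ids=snp_ids,
        chroms=["3"] * m,
        positions=positions,
        dosages=dos,
    )
    cfg = config
    if cfg.beta_snp != 0.0 and cfg.causal_snp is None:
        # default: first simulated SNP carries the effect
        cfg = SimConfig(**{**asdict(config), "causal_snp": snp_ids[0]})
    pheno, truth = simulate_longitudinal(ped, geno, cfg, rng, K=K)
    if cfg.medication_model == "threshold":
        pheno = apply_medication(
            pheno, cfg.medication_threshold, cfg.treatment_effect, rng, truth=truth
        )
    return ped, K, geno, pheno, truth


def with_ld_twins(
    geno: GenotypeDosages, target_r2: float, rng: np.random.Generator
) -> GenotypeDosages:
    """Interleave a noisy copy of every SNP to create LD pairs.

    Each twin is the original dosage plus Gaussian noise scaled so the
    squared correlation is approximately ``target_r2`` (clipping to
    [0, 2] perturbs it slightly), placed one base pair downstream.
    Exercises LD pruning; the default generator otherwise simulates
    independent SNPs.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    snp_ids, chroms, positions, cols = [], [], [], []
    for j in range(geno.n_snps):
        d = geno.dosages[:, j]
        sd = d.std()
        noise_sd = sd * np.sqrt((1.0 - target_r2) / target_r2)
        twin = np.clip(d + rng.standard_normal(d.shape[0]) * noise_sd, 0.0, 2.0)
        snp_ids += [geno.snp_ids[j], f"{geno.snp_ids[j]}_twin"]
        chroms += [geno.chroms[j]] * 2
        positions += [int(geno.positions[j]), int(geno.positions[j]) + 1]
        cols += [d, twin]
    return GenotypeDosages(
        ids=geno.ids, snp_ids=snp_ids, chroms=chroms,
        positions=np.asarray(positions, dtype=np.int64),
        dosages=np.column_stack(cols),
    )


def write_pheno_tsv(tbl: pd.DataFrame, path) -> None:
    tbl.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_pheno_tsv(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"pedigree_id": str, "individual_id": str})
    required = {"pedigree_id", "individual_id", "visit", "age", "sex", "smoke", "medicated", "trait"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return tbl
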