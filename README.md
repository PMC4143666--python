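# kinlong

Kinship-structured baseline and longitudinal association testing for
quantitative traits in extended pedigrees.

Family studies that measure a trait such as blood pressure at several
exams pose a double correlation problem for GWAS: repeated measures are
correlated within a person, and people are correlated within a
pedigree. `kinlong` implements and compares four mixed-model
association strategies that share one covariance assumption — a
person-level random intercept whose covariance is proportional to the
pedigree kinship matrix — together with everything needed to evaluate
them without access to restricted cohort data: a pedigree/kinship
engine, a synthetic-data generator, blood-pressure-style trait
preprocessing, and power / type-I-error machinery.

## The models

With pedigree *i*, individual *j*, exam *t*, covariates
X<sub>ijt</sub> and SNP dosage SNP<sub>ij</sub> ∈ [0, 2]:

| method     | model                                                                  | data per person | criterion |
|------------|------------------------------------------------------------------------|-----------------|-----------|
| `baseline` | Y<sub>ij0</sub> = β₀ + X<sub>ij0</sub>β + β<sub>s</sub>SNP<sub>ij</sub> + α<sub>ij</sub> + ε<sub>ij</sub> | first exam only | ML |
| `lme`      | Y<sub>ijt</sub> = β₀ + X<sub>ijt</sub>β + β<sub>s</sub>SNP<sub>ij</sub> + α<sub>ij</sub> + ε<sub>ijt</sub> | all exams | REML |
| `mean`     | Y<sub>ij*</sub> = β₀ + X<sub>ij*</sub>β + β<sub>s</sub>SNP<sub>ij</sub> + α<sub>ij</sub> + ε<sub>ij</sub> | means over exams | ML |
| `twostage` | stage 1: Y<sub>ijt</sub> = β₁₀ + X<sub>ijt</sub>β + α<sub>ij</sub> + ε<sub>ijt</sub>; stage 2: α̂<sub>ij</sub> = β₂₀ + β<sub>s</sub>SNP<sub>ij</sub> + γ<sub>ij</sub> + ε<sub>ij</sub> | BLUPs | ML |

In every model the person-level random vector per pedigree is
N(0, σ²Σ<sub>kin</sub>) with Σ<sub>kin</sub> the (numerator)
relationship matrix, block-diagonal by pedigree, and the per-SNP test
is a Wald test of β<sub>s</sub>. Stage 1 of the two-stage method is
SNP-independent and fitted once, which makes it the cheapest per-SNP
strategy. A fast mode (variance components frozen at the no-SNP null
fit, GRAMMAR/EMMAX style) serves genome-scale scans; the default exact
mode refits variance components per SNP.

## Worked example

```python
import kinlong as kl

cfg = kl.SimConfig(
    n_pedigrees=125, pedigree_template="sibship(4)",
    mafs=(0.3,), beta_snp=0.38, seed=11,
)
ped, K, geno, pheno, truth = kl.simulate_dataset(cfg, n_snps=1)
res = kl.run_all(pheno, geno, K, trait_kind="sbp_like", impute=False)
print(res[["snp_id", "method", "effect", "se", "p"]].to_string(index=False))
```

prints

```
   snp_id   method   effect       se        p
3_1000000 baseline 0.386629 0.101275 0.000135
3_1000000      lme 0.344666 0.078897 0.000013
3_1000000     mean 0.360431 0.075903 0.000002
3_1000000 twostage 0.202255 0.045915 0.000011
```

One causal SNP (true effect 0.38 trait units per dosage) in 125
four-sibling pedigrees: the three longitudinal methods, which use all
four exams, estimate the effect with a ~25% smaller standard error
than the baseline (single-exam) analysis and reach p-values one to two
orders of magnitude smaller. The two-stage effect size is
attenuated (it is a regression on shrunken BLUPs) but its evidence
tracks the longitudinal mixed model closely. The same pipeline runs
from the shell:

```sh
kinlong simulate --n-pedigrees 125 --template 'sibship(4)' --n-snps 100 \
    --seed 11 --out-prefix study
kinlong assoc --fam study.fam --geno study.dosages.tsv \
    --pheno study.pheno.tsv --method all --out results.tsv
kinlong evaluate lambda --results results.tsv
```

Inputs are PLINK FAM pedigrees, VCF (DS dosage field) or TSV dosage
matrices, and a person-visit phenotype TSV. Preprocessing mirrors
blood-pressure practice: treated observations are imputed to the mean
of all strictly higher same-sex values within ±10 years of age,
covariates are age/sex/smoking (plus centered age² for DBP-like
traits), and covariate screening keeps candidates with p < 0.05 in the
kinship model.

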