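# Methods

## Kinship and covariance structure

Pedigrees are read from PLINK FAM/PED text (missing parent `"0"`, sex
1 = male / 2 = female; other codes rejected). Kinship coefficients are
computed by the standard recursion in topological order (Kahn's
algorithm; ties broken by input row order for determinism):
φ<sub>jj</sub> = ½(1 + φ<sub>fm</sub>) and
φ<sub>jk</sub> = ½(φ<sub>kf</sub> + φ<sub>km</sub>), which handles
inbreeding loops exactly. The exported matrix defaults to the
numerator-relationship scale 2φ, so the variance component that
multiplies it is the additive genetic variance on its natural scale;
the raw φ scale is available, and the two differ only by a factor of 2
absorbed in σ². Relatedness between pedigrees is taken to be zero, so
Σ<sub>kin</sub> is block-diagonal by pedigree and every model
factorizes over pedigrees. Individuals appearing only as parents are
materialized as founders with a warning (a strict mode errors
instead).

The recursion is validated against an independent Monte-Carlo oracle:
gene dropping with uniquely labelled founder alleles, estimating each
pairwise kinship as the probability that randomly drawn alleles are
identical by descent. On a 20-member three-generation pedigree with a
full-sib mating, recursive values agree with 10⁵ drops within three
Monte-Carlo standard errors for every pair.

## The mixed-model engine

All four association strategies are instances of

y ~ N(Xβ, σ² · Z Σ<sub>kin</sub> Zᵀ + σ<sub>ε</sub>² · I),

with Z the person incidence matrix (identity for person-level models).
Fitting profiles β and the overall scale out of the likelihood and
searches the single variance ratio δ = σ²/σ<sub>ε</sub>²: each
pedigree block of Z Σ<sub>kin</sub> Zᵀ is eigendecomposed once, after
which every likelihood evaluation is O(n). The ratio is located on a
64-point log grid spanning [10⁻⁶, 10⁶] plus the δ = 0 boundary, then
refined by bounded Brent search (tolerance 10⁻⁸ on log δ); fits ending
at the grid edge are flagged as boundary fits rather than raised.
ML and REML criteria are both available; the per-method defaults are
REML for the longitudinal mixed model and ML everywhere else. A
profiled optimum is verified in the tests against brute-force dense
grid maximization (agreement ~10⁻⁶, asserted at 10⁻⁴). The dense
oracle grids over (total scale, kinship proportion h ∈ [0, 1]) rather
than (σ², σ<sub>ε</sub>²) so that boundary optima lie on the grid, and
its first sweep is dense because the profiled surface can be
multimodal in h.

Fixed-effect standard errors come from the inverse expected information
of the GLS step at the variance-component optimum (variance-component
uncertainty is not propagated, the usual practice at these sample
sizes). The residual scale entering the standard errors uses the
residual-df-corrected estimator S/(n−p) under both criteria; using the
ML scale S/n instead inflates every Wald χ² by ≈ n/(n−p), which is
visible as a ~1% genomic-control shift at n = 750. Per-SNP inference
is a Wald z with a normal reference (equivalently χ²₁); no small-sample
t correction is applied.

Predicted random intercepts (BLUPs) are
α̂ = σ̂² Σ<sub>kin</sub> Zᵀ V̂⁻¹(y − Xβ̂), computed per pedigree block
and validated against the dense formula at 10⁻⁸.

Two per-SNP modes exist. Exact mode refits the variance components
for every SNP. Fast mode fits the no-SNP null model once, freezes the
variance ratio, and tests each SNP by weighted least squares in the
rotated coordinates with the residual scale re-estimated per SNP —
the GRAMMAR/EMMAX approach. On 100 null SNPs at the 750-person study
scale the two modes' p-values agree to 0.1% at the median and within
5% for ~97% of SNPs; the discrepancy concentrates in the far tail,
where small z differences are amplified multiplicatively, so a uniform
closeness bound on p-ratios is not attainable and the agreement test
is stated distributionally. Fast mode is the default only for the
genome-scale calibration runs; association runners default to exact.

## Trait preprocessing

Antihypertensive-treatment masking is handled by imputation: a treated
person-visit with observed value v, sex s and age a is replaced by the
mean of all person-visit observations with sex s, age in the closed
window [a−10, a+10] and value strictly greater than v. Pools are
formed from pre-imputation values of all other subjects' observations
(the subject's own visits are excluded); an empty pool retains the
observed value with a logged warning. The imputed value can therefore
never fall below the observed one. The pool definition — comparison
against the subject's own observed value, pools containing raw values
of treated and untreated subjects alike — is the one reading under
which the rule is well-defined per exam; it is an assumption of this
package, not an external fact.

Baseline extraction takes each individual's minimum-visit row with its
covariates; the mean-measure view averages the trait and every
time-varying covariate (age, smoking) over the individual's observed
visits and passes time-invariant covariates through. SBP-like traits
adjust for age, sex and smoking; DBP-like traits add centered age²,
with the centering mean computed over the rows of whichever analysis
table is in use (baseline table for the baseline method, and so on).
Covariate screening tests each candidate as the sole fixed effect in
the kinship random-intercept model and keeps those with Wald p < 0.05.

## Synthetic data

The generator emulates an extended-family longitudinal blood-pressure
study: configurable pedigree templates (sibship(k) / nuclear(k) with
founder parents, or a 14-member three-generation family), up to 4
visits at a fixed 5-year gap (the defaults), optional
missing-completely-at-random dropout that truncates follow-up, and a
trait built as

y<sub>ijt</sub> = β₀ + β·x<sub>ijt</sub> + β<sub>s</sub>·SNP<sub>ij</sub> + g<sub>ij</sub> + a<sub>ij</sub> + e<sub>ijt</sub>

with polygenic g ~ N(0, σ<sub>g</sub>² Σ<sub>kin</sub>) drawn per
pedigree block, person-level a ~ N(0, σ<sub>a</sub>²) i.i.d., and
occasion noise e ~ N(0, σ<sub>e</sub>²) i.i.d. per visit. Default
variance components are σ<sub>g</sub>² = 0.5, σ<sub>a</sub>² = 0.5,
σ<sub>e</sub>² = 2.0 (trait units²) — occasion noise deliberately
dominates, which is the regime in which repeated measures pay off.
Genotypes come from gene dropping: founders draw two alleles
Bernoulli(MAF), children inherit one uniformly random allele per
parent, so dosages are Mendelian-consistent integers with the additive
correlation structure 2φ — this same machinery doubles as the kinship
oracle. SNPs are independent common variants (MAF ∈ [0.05, 0.5]); an
optional copy-with-noise mode appends a correlated twin per SNP at a
target r² to exercise LD pruning. Medication is modelled as a
threshold rule — visits whose latent trait exceeds t are flagged and
reduced by a fixed treatment effect (default 10 units) — the minimal
model that makes the imputation rule testable; latent values are kept
in the truth record.

What the generator does **not** emulate: realistic LD maps and allele
frequency spectra, rare variants, ascertainment of pedigrees,
informative dropout, age-dependent variance components, measurement
protocols that differ across exams. Passing tests therefore establish
internal statistical correctness of the methods under their assumed
covariance structure, not robustness to the many ways real cohort data
violate it.

One structural consequence matters for interpretation: the generator's
person-level effect has covariance σ<sub>g</sub>²Σ<sub>kin</sub> +
σ<sub>a</sub>²I, while the longitudinal model fits a single kinship
component plus observation noise. The longitudinal fit is therefore
(mildly) misspecified by design, and its variance components have no
direct truth to recover — measured consequence: it runs slightly
conservative (λ ≈ 1.00, never inflated). Averaging the visits removes
the mismatch exactly: the per-person mean model is correctly specified
with kinship variance σ<sub>g</sub>² and residual variance
σ<sub>a</sub>² + σ<sub>e</sub>²/v for v visits, which is how parameter
recovery is defined and tested (medians over 200 datasets within 10%
for variance components and 5% for the SNP effect).

## Evaluation machinery

MAF filtering keeps SNPs with folded frequency ≥ 0.05 (inclusive),
frequency estimated as mean dosage / 2. LD pruning scans in position
order and keeps a SNP iff its squared dosage correlation with every
previously kept SNP within a 50-SNP window is below the threshold
(default r² = 0.2); zero-variance SNPs are skipped with a warning.
Window size and retention rule are package choices — pruned counts are
only meaningful relative to them. The multiple-testing threshold used
throughout the power experiments is 0.05/25,676 ≈ 1.947 × 10⁻⁶, the
Bonferroni level for the approximate number of LD-independent common
SNPs on chromosome 3 that the study design targets. Genomic control
uses the median estimator λ = median(χ²)/0.4549 with the χ² values
obtained from p through the same tail function as the reference
median, so constant p = 0.5 gives λ = 1 exactly. Power is the
proportion of replicates whose causal-SNP p-value beats the threshold,
with Wilson 95% intervals (better small-count coverage than Wald).

A single 20,000-SNP dataset determines λ only to about ±0.017 (the
sampling noise of a median), so calibration claims below that
resolution are tested by pooling independent replicates of the same
simulation; the headline λ reported by `scripts/acceptance.py` is the
stipulated single-dataset quantity.

## Problem sizes and numerical choices

The shipped experiments use 125–200 pedigrees (750–1,200 individuals),
4 visits, 20,000 null SNPs for calibration and 200 replicates for
power — sizes chosen so the full suite and the acceptance script each
run in a few minutes on one core while leaving the Monte-Carlo error
of every asserted quantity well inside its test band. Degenerate
inputs are handled explicitly: exact-fit data (residual sum of squares
at machine zero) floor the variance and flag the fit; monomorphic SNPs
return p = 1 with a flag rather than an error; a stage-1 fit with zero
kinship variance shrinks all BLUPs to zero and the two-stage scan
reports every SNP as uninformative; p = 0 is clamped to the smallest
positive float on export with a logged count.

## Known limitations

- One kinship-structured random intercept plus i.i.d. residual; no
  random slopes, no simultaneous extra variance components (beyond the
  two-component person-level case used by stage 2), no non-Gaussian
  traits.
- Wald inference with a normal reference; no small-sample t or
  Kenward–Roger-style corrections, no likelihood-ratio tests.
- Individual ids must be globally unique across pedigrees to index
  genotypes and kinship (the generator guarantees this; readers
  validate it).
- LD pruning is the greedy windowed heuristic, not an exact maximum
  independent set; slope-type two-stage statistics are deliberately
  out of scope (mean-type statistics are the more powerful choice for
  level effects).
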