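# Methods

## The model

`qltdt` tests whether a SNP is associated with a (possibly multivariate)
quantitative phenotype using allelic transmissions in nuclear families.
The test conditions transmission on phenotype (a retrospective design), so
it makes no assumption about the marginal or joint distribution of the
phenotype values across time points.

For each SNP, every nuclear family with at least one heterozygous parent is
*informative*. For offspring *j* with phenotype vector **Y**_j (length *k*),
let *Z_j* indicate whether the designated heterozygous parent transmitted
the minor allele (father, when both parents are heterozygous) and *W_j*
whether the other parent did. Both indicators get logistic mean models with
a shared phenotype coefficient vector γ:

    E[Z_j | Y_j] = expit(α₁ + γᵀY_j)
    E[W_j | Y_j] = expit(α₂ + γᵀY_j)

Under no association, Mendelian segregation gives E[Z_j] = 1/2, i.e.
α₁ = 0 and γ = 0. The parameters are estimated from quasi-score (GEE-type)
equations Σ_j D_jᵀ V_j⁻¹ (X_j − λ_j) = 0 with diagonal Bernoulli working
variances λ(1−λ), solved by Fisher scoring with step-halving from θ = 0
(tolerance 1e-8 on the score norm, at most 100 iterations). Association is
a Wald test of H₀: γ = 0 with k degrees of freedom.

Two intercepts are used (α₁ for the Z link, α₂ for the W link) because the
designated and the other parent are not exchangeable: the other parent may
be homozygous, in which case its transmission is deterministic and its
marginal mean reflects the allele frequency rather than fair segregation.
Separate intercepts keep the k-df test on γ clean.

### Why the W channel matters — and what it costs

In `het_only` mode (the classical TDT reading) only unambiguous Z
contributions enter, every one a fair Bernoulli(1/2) draw under the null
regardless of population structure; the test is robust to stratification
but discards information. In `both_parents` mode the other parent's
transmissions are included *even when deterministic*: a homozygous-minor
parent always transmits the minor allele, so the W channel carries
allele-frequency information correlated with the offspring's genotype and
hence, under an additive effect, with the phenotype. This is the source of
the power gain of the both-parents test — and of its susceptibility to
population stratification, where allele frequency and phenotype level are
confounded between subpopulations. Both behaviours are reproduced
quantitatively by the simulation harnesses (see below).

Edge cases in the (Z, W) encoding:

- Other parent homozygous: W is deterministic (0 or 2 minor alleles →
  W = 0 or 1). The component stays in the estimating function with the
  model's working variance, which is positive at any finite parameter
  value.
- Both parents heterozygous, child heterozygous: the individual
  transmissions are unidentifiable; the offspring contributes through the
  observed total S = Z + W = 1, with mean expit(α₁+γᵀY) + expit(α₂+γᵀY)
  and variance the sum of the two Bernoulli variances. This uses exactly
  what is observed without imputing an assignment.
- Mendelian-inconsistent offspring are dropped from that variant's unit
  with a logged warning; the family's remaining offspring are kept.

### Covariance estimation and small-sample inference

Deterministic W values are shared by all siblings of a homozygous parent,
so residuals are strongly correlated within a family and offspring cannot
be treated as independent units in the robust covariance. The sandwich
A⁻¹BA⁻¹ therefore accumulates B over *nuclear families* by default
(`cluster="offspring"` restores per-offspring units for the het-only
setting, where it is justified).

With ~130 informative-family clusters, two standard GEE small-sample
corrections are applied by default:

1. **Mancl–DeRouen leverage adjustment**: each cluster's residuals are
   premultiplied by (I − H_c)⁻¹ before forming B, removing the downward
   plug-in bias of the empirical covariance.
2. **F reference with cluster degrees of freedom**: the quadratic form
   T = γ̂ᵀ vcov_γγ⁻¹ γ̂ is referred to F(k, ν−k+1) after scaling by
   (ν−k+1)/(νk), with ν = (number of clusters) − 1, and the reported
   statistic is the χ²_k quantile of the resulting p-value. The identity
   p = χ²_k.sf(statistic) is preserved, and the statistic is
   χ²-calibrated at any cluster count. As ν → ∞ this reduces to the
   ordinary Wald statistic; both corrections can be switched off
   (`bias_correction=False`, `small_sample=False`).

Monte-Carlo verification (3,000 null replicates per master seed, default
design): empirical size 0.050–0.056 at nominal 0.05, KS agreement with
χ²₂ not rejected. Without the corrections the size is 0.067 (family
clustering) to 0.091 (offspring clustering).

Degenerate inputs: constant phenotype columns are rejected (γ would be
confounded with the intercepts); complete separation (all Z identical, or
all W identical when W components exist) and parameter drift beyond ±30
are flagged and the variant is reported with status `degenerate`, never
crashing a scan.

## Phenotype preparation

Raw trait values (triglyceride-like primary trait, HDL-like covariate
trait; four time points each) are natural-log transformed; a one-sample
Kolmogorov–Smirnov check against a normal with plug-in mean/sd is logged
per column. The plug-in makes the classical KS p-value anti-conservative
(the Lilliefors situation), so the check is advisory — it never gates the
pipeline.

Missing cells are handled in two stages, assuming an ignorable (MCAR/MAR)
mechanism:

1. **EM on founders**: maximum-likelihood mean vector and covariance
   matrix of the joint (trait + covariate) log-scale columns, estimated on
   founders only — founders are the independent draws from the
   population, whereas offspring values share family effects. The E-step
   uses exact conditional moments per missingness pattern; convergence is
   declared when the observed-data log-likelihood changes by < 1e-8
   (at most 500 iterations); the likelihood trajectory is recorded and is
   nondecreasing by construction of EM. Initialisation is available-case
   means and pairwise covariances projected to the nearest positive
   semidefinite matrix. Covariances use the ML (1/n) denominator
   throughout.
2. **Plug-in conditional imputation for everyone** (founders' own missing
   cells included): missing block = μ_m + Σ_mo Σ_oo⁻¹ (y_o − μ_o);
   observed entries are untouched; an all-missing row receives the mean
   vector; a singular observed block falls back to the pseudo-inverse
   with a warning.

Covariate adjustment regresses each trait time point on all four
covariate time points plus an intercept, fitted on founders only by OLS;
residuals are computed for every individual from the founder-fitted
coefficients. All four covariate time points are used as regressors (one
equation per trait time point) since cross-time confounding is plausible
and the four coefficients are cheap to estimate on 100+ founders.

Phenotype definitions summarise the treatment design (drug administered
between time points 2 and 3):

| name | k | adjusted | content |
|---|---|---|---|
| TBATPre | 1 | no | PC1 of log trait, time points 1–2 |
| TBATPost | 1 | no | PC1 of log trait, time points 3–4 |
| MTBAT | 2 | no | (TBATPre, TBATPost) stacked |
| *Adj variants | — | yes | same, on covariate-residualised values |

PC1 scores are projections of column-centred data onto the leading
eigenvector of the 2×2 sample covariance; the eigenvector sign is fixed so
its component sum is positive (first component positive on a tie), making
scores reproducible across platforms. Scores have mean zero and variance
equal to the leading eigenvalue.

## Variant and family filters

- Minor-allele orientation: if the counted allele's frequency among
  founders exceeds 0.5 the variant is flipped so dosage always counts the
  minor allele; a tie (exactly 0.5) keeps the original orientation, which
  makes orientation idempotent. MAF is computed on founders only, to
  avoid double-counting transmitted alleles.
- Variants that are monomorphic or have founder MAF < 0.05 are excluded
  (strict inequality: MAF exactly 0.05 is retained); every exclusion is
  logged with its reason.
- A variant is testable only with strictly more than 20 informative
  families (≥ 21). Families with a missing parental genotype are skipped
  for that variant.

The genome scan emits one row per (variant × phenotype definition),
applies Benjamini–Hochberg step-up FDR control at level 0.05 *within each
definition* across rows with a valid p-value (untested/degenerate variants
are excluded from m), and sorts output by (chromosome, position,
definition) so results are invariant to input variant order.

## The synthetic-data generator

`simulate_dataset` emulates a lipid-lowering-drug family study design:

- 200 nuclear families; offspring per family uniform on {2..8} (expected
  total 1,000 offspring, matching the ~990 of the emulated design).
- Parents drawn under Hardy–Weinberg at MAF 0.3; offspring genotypes by
  fair Mendelian gamete draws, so the transmission null is exact.
- Log-scale trait model per individual and time point *t*:
  μ_t + a·dosage + d·1{t≥3} + b·(covariate_t − μ_cov) + family intercept
  (offspring only, sd 0.3) + exchangeable noise (sd 0.5, ρ 0.5); the raw
  trait is the exponential. Defaults: μ_t ≈ 4.7 (log mg/dL scale),
  d = −0.25 (treatment lowers the trait at time points 3–4), b = −0.3
  (the covariate trait tracks the primary trait negatively, as HDL does
  triglycerides), covariate sd 0.3 / ρ 0.5 around means ≈ 3.9.
- Per-column missingness emulating the availability pattern of the
  emulated study (trait: 27%, 0%, 44%, 26%; covariate: 27%, 0%, 28%,
  22% — heaviest at time point 3).
- Optional two-subpopulation stratification scenario: families split
  evenly, MAFs 0.1 vs 0.5, log-trait shift δ = 0.6 in the
  high-frequency subpopulation — allele frequency and phenotype level are
  deliberately confounded.
- A single master seed spawns named substreams (structure, genotypes,
  phenotypes, missingness); identical configs give byte-identical output
  files. The truth record stores every latent log-scale value, so any
  phenotype cell can be re-derived exactly.

What the generator does **not** emulate: linkage disequilibrium between
variants, a realistic allele-frequency spectrum, genotyping error,
parent-of-origin effects, or trait dynamics richer than a mean shift.
Passing calibration and power checks therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on any
particular real cohort.

## Calibration and power harnesses

`simulate_null_statistics` and `simulate_power_curve` run the in-memory
pipeline (simulate → log transform → PC construction → encode → fit →
Wald) once per replicate on a single variant. They use a configuration
with missingness switched off (`calibration_config`): statistic
calibration is deliberately separated from imputation, which has its own
exact and simulation checks. Power comparisons are paired — the same
replicate is analysed under both modes — so mode contrasts share
Monte-Carlo noise.

Headline Monte-Carlo results (recomputed by `scripts/acceptance.py`;
values from seed 1): null size 0.051 (2,000 replicates, 99% band
[0.037, 0.063]), KS-vs-χ²₂ p = 0.32; power at the calibrated effect
a = 0.09 log-units/allele: 0.571 (both parents) vs 0.543 (het only),
1,000 paired replicates; stratified null size 0.603 (1,000 replicates) in
both-parents mode, while het-only stays at the nominal level. The effect
size a = 0.09 was calibrated once to put power in the 50–70% range, where
mode differences are visible.

## Numerical conventions and limitations

- Natural logarithms throughout; ML (1/n) covariance denominators.
- Fisher scoring starts at θ = 0 and uses step-halving on the score norm.
- Float output in result TSVs uses 6 significant digits; re-reading a
  written table reproduces it to that precision.
- Working independence across families is assumed (the test is valid in
  the presence of linkage only under the stated
  transmissions-uncorrelated-within-family assumption); a
  `correlated_transmissions` generator scenario exists to explore
  violations, default off.
- No genotype imputation, no phasing, no X/Y/MT handling, no
  multi-generation pedigree decomposition beyond nuclear families, no
  gene/cytoband annotation, no linear-mixed-model alternative.
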