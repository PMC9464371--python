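# Methods

## Overview

`pleioscan` tests whether single genetic variants influence both systemic
inflammation (C-reactive protein, CRP) and adiposity (body-mass index, BMI;
sex-stratified waist-to-hip ratio, WHR ×100), and, for variants that do,
asks whether the sharing reflects *biologic pleiotropy* (independent direct
effects) or *mediated pleiotropy* (an effect on one trait transmitted
through the other). The pipeline is: phenotype preparation → univariate
GWAS per study → fixed-effect inverse-variance meta-analysis → adaptive
Sum of Powered score (aSPU) multi-trait test on the meta-analyzed Z-scores
→ LD clumping and candidate/replication decision rules → causal mediation
decomposition. A synthetic-cohort generator with known ground truth drives
every stage, so the statistical behaviour of the whole chain is testable
without access to individual-level consortium data.

## Phenotype preparation

The four analysis traits are CRP (natural-log scale), BMI, WHR-men and
WHR-women, with WHR = 100·waist/hip. The fixed order is:

1. transform (log for CRP);
2. single-pass outlier exclusion: |value − mean| > k·SD with k = 3 for
   log-CRP and k = 4 for BMI/WHR, mean and SD computed once on the
   non-missing values (no iterative re-flagging);
3. least-squares residualization on age, age², sex (where applicable),
   BMI (WHR models only), center/cohort indicators and age×sex;
4. rank-based inverse normal transform (INT), Φ⁻¹((rank − ½)/n), average
   ranks for ties. The ½ offset (rankit) avoids ±∞ and is the common GWAS
   choice; the Blom offset 3/8 is available via `offset=0.375`.

Outlier exclusion precedes residualization because excluded observations
should not influence the covariate fit. Collinear design columns are
dropped by pivoted QR with a logged warning; the reference level of each
categorical is the alphabetically first.

## Univariate association and meta-analysis

Per SNP, the INT trait is regressed on dosage plus the leading genetic
principal components (10 by default). Family structure is handled as in
GEE with an independence working correlation: the point estimate is OLS
and the variance is the cluster-robust sandwich grouped by family id
(HC0-type, no small-sample correction), which reduces exactly to the
heteroskedasticity-robust variance when all clusters are singletons. The
per-SNP coefficient and sandwich are computed by Frisch–Waugh partialling
of both outcome and dosage on the covariates, which reproduces the
full-model coordinate exactly and vectorizes across the whole panel; a
test cross-checks it against `statsmodels` GEE. Wald z and two-sided
normal p-values are reported.

SNP-level QC drops records with imputation quality < 0.4, minor allele
frequency < 0.05 or effective sample size < 30, all strict inequalities.
Effective N is 2·eaf·(1−eaf)·N·info, the standard information-content
adjustment for imputed dosages; the formula is configurable.

Per-study estimates are pooled with fixed-effect inverse-variance weights
(w = 1/SE², exactly-rounded sums so pooling is order-invariant), after
aligning alleles to the first study carrying each SNP: swapped alleles
flip the sign, strand flips are resolved by complementing, and ambiguous
A/T-C/G SNPs are oriented by allele-frequency proximity and dropped when
the frequencies disagree by more than 0.2. Genomic inflation is the usual
λ = median(χ²)/0.4549.

## The aSPU multi-trait test

For one SNP with Z-scores S_p over K traits, SPU(γ) = Σ_p S_p^γ for
γ ∈ {1, …, 8}. γ = 1 pools dense, same-signed signal; larger γ
concentrates weight on the strongest traits; the adaptive statistic is
min_γ p_γ. Odd-γ statistics are compared by |SPU| because the sign of a
Z-score is an allele-coding convention. The γ = ∞ (max-|Z|) variant is
available behind a flag but excluded from the default grid.

Null draws are multivariate normal with the between-trait correlation R of
null Z-scores, estimated from the genome-wide summary statistics: SNPs
with |z| < 2 on every available trait, thinned to every 100th in position
order (an LD-pruning stand-in; on LD-free synthetic panels thinning is set
to 1), pairwise-complete Pearson correlation, ridge-repaired toward the
identity if numerically non-positive-definite. The |z| < 2 truncation
biases the estimate toward zero; a test quantifies the bias against a
truncated-MVN simulation oracle, and the type-I calibration test shows the
procedure is calibrated despite it.

Monte-Carlo p-values use the add-one estimator p = (1+x)/(B+1), so p ≥
1/(B+1) always. Per-γ p-values count null |SPU| draws at or above the
observed value. The adaptive p-value ranks each draw's min-γ p against
all B draws; the comparison "draw minimum ≤ observed minimum" is carried
out in exact integer rank arithmetic, so the vectorized O(B log B)
implementation, the two-pass streaming implementation used at large B
(which keeps only exceedance counts and the top-k order statistics per γ)
and a naive O(B²) re-ranking oracle all agree bit-for-bit on a shared,
reproducible chunked draw stream.

A staged schedule (default B = 10⁴ → 10⁶ → 10⁸) evaluates every SNP at
the first stage and escalates SNPs with p ≤ c/B (c = 100) to the next.
Draw streams are keyed per (stage, availability mask), so SNPs sharing a
mask share null draws and results are independent of processing order.
SNPs missing a trait are scored over the available traits with the
matching submatrix of R. The top stage of 10⁸ is what allows the
Monte-Carlo floor to fall below the candidate threshold of 1.25×10⁻⁸;
replication scans stop at 10⁶ because their decisions only require
nominal (0.05) resolution.

## Locus selection and replication

Greedy clumping: take the SNP with the smallest multi-trait p as a lead,
absorb all SNPs within 1 Mb with r² ≥ 0.1 (dosage Pearson r²), repeat.
The window bounds compute cost; the r² rule defines independence. The
candidate rule for a lead SNP is the conjunction of:

- multi-trait p < 1.25×10⁻⁸ (genome-wide 5×10⁻⁸ divided by the 4 traits);
- univariate CRP p < 0.05 **and** at least one adiposity trait p < 0.05;
- presence in the pooled genotyping panel (a boolean column supplied by
  the pipeline).

Replication requires multi-trait p < 0.05, nominal CRP and ≥ 1 nominal
adiposity trait, and discovery/replication sign agreement on every trait
that contributed to the nominal-support criterion. Applying the sign rule
only to the contributing traits (rather than all four) was a genuinely
open choice; a sign flip on a trait with no replication signal is noise.

## Causal mediation

For each replicated SNP, prior knowledge assigns the direction: an
inflammation-prior SNP is tested with CRP as mediator and the adiposity
trait as outcome, and conversely. Two linear models are fit on complete
cases with HC0 sandwich covariances and no mediator×genotype interaction:
mediator ~ genotype + covariates (age, sex, 10 PCs) and outcome ~
mediator + genotype + covariates. Quasi-Bayesian simulation draws 1000
parameter vectors from N(estimate, robust vcov) per model; per draw
ACME = a·b, ADE = c′, total = ACME + ADE (exact in the linear
no-interaction case). Percentile 95% CIs and two-sided Monte-Carlo
p-values (doubled tail fraction, capped at 1) summarize the draws.

Point estimates are the analytic products of coefficients rather than
draw medians: additivity (total = ADE + ACME) and agreement with the
sensitivity curve at ρ = 0 then hold to machine precision, and with 1000
draws the median differs from the analytic value only by Monte-Carlo
noise. Medians are still reported alongside.

Sensitivity to unmeasured mediator–outcome confounding uses the
linear-structural-equation identity: with ε₁ the mediator-model residuals
and ε₂ the reduced-form outcome residuals (mediator omitted), second
moments s₁₁, s₁₂, s₂₂, the bias-corrected mediator coefficient at error
correlation ρ is b(ρ) = (s₁₂ − ρ·√((s₁₁s₂₂ − s₁₂²)/(1 − ρ²)))/s₁₁ and
ACME(ρ) = â·b(ρ). The curve crosses zero exactly at the observed residual
correlation ρ* = s₁₂/√(s₁₁s₂₂). Only the continuous/continuous case is
implemented, matching the analyses the pipeline performs.

## Synthetic cohorts

The generator emulates the structure the analysis assumes rather than any
particular population:

- genotypes: Binomial(2, MAF) per individual (Hardy–Weinberg), MAF ∈
  (0, 0.5]; LD pairs on demand by a latent bivariate-Gaussian threshold
  construction with the attainable correlation bound reported on error;
- covariates: age ~ U(18, 80), sex ~ Bernoulli(0.63 female), standard
  normal PCs, a small number of centers — placeholder distributions with
  fixed, documented covariate effects for the prep stage to remove;
- family structure: cluster sizes drawn from {1: 0.7, 2: 0.2, 3: 0.1},
  an additive Gaussian random intercept per cluster with variance 10% of
  the residual variance per trait;
- traits: log-CRP, BMI and latent WHR are linear in dosage, covariates
  and the cluster effect with jointly normal errors (default correlation
  0.30/0.25/0.45 among log-CRP/BMI/WHR); CRP = exp(log-CRP), floored at
  1e-4 (assay detection limit); hip ~ N(100, 6) and waist = hip·WHR/100,
  so WHR is recoverable exactly;
- effect classes: *pleiotropic* (direct betas on log-CRP and one
  adiposity trait), *mediated* (one direct beta; the effect reaches the
  other trait through a mediation coefficient, default 0.3, applied to
  the standardized mediated channel), *single_trait*, *null*. The
  mediated channel carries the mediated-class SNPs' genetic contribution
  plus the mediator's own cluster/error variation — so mediated SNPs show
  a genuine indirect path recoverable by the mediation module, while
  pleiotropic and single-trait SNPs keep clean ground-truth semantics.
  Directions that would form a cycle (a trait both feeding and receiving
  CRP mediation) are rejected.

Residual SDs default to 1.0 for all three traits. Because the GWAS
outcome is the INT residual, per-allele effects on the generating scale
are recovered on the INT scale only when the residual SD is ≈ 1; this
keeps recovery tests interpretable. Means are realistic (log-CRP 0.94,
BMI 29.2, WHR in the low 90s) but the spread is standardized, and no
attempt is made to match real allele-frequency spectra, genome-wide LD,
or imputation-uncertainty patterns: passing tests demonstrate the
statistical machinery, not population realism.

## Problem sizes and numerical choices

The demonstration configuration is n = 2000 discovery / 1000 replication
individuals, m = 5000 SNPs (4 pleiotropic, 3 single-trait, 2 mediated,
rest null) at effect size 0.35 per allele, aSPU schedule 10⁴ → 10⁶ →
10⁸ — sizes chosen so a full run completes in minutes on one core while
still exercising every decision rule, including the 1.25×10⁻⁸ threshold.
Acceptance-style property checks use 2000 null SNPs for type-I
calibration (binomial band [0.040, 0.061] at α = 0.05), B = 10⁶ for
χ²-oracle agreement within 3 Monte-Carlo SEs, and 200 replicates at
n = 5000 for mediation CI coverage (band [0.90, 0.985]).

Degenerate inputs are handled explicitly: constant phenotype vectors flag
no outliers (SD = 0); monomorphic SNPs are emitted with beta = 0 and a
boundary EAF so QC removes them; non-positive-definite correlation inputs
raise, while estimated null correlations are ridge-repaired with a
warning; ties in INT use average ranks; ties in Monte-Carlo ranking are
handled by the integer count convention shared across all three aSPU
implementations.

## Known limitations

- The GEE working correlation is independence only; no mixed-model GWAS,
  no X-chromosome handling.
- Null-correlation thinning is a stand-in for LD pruning, not an LD model.
- Mediation handles one continuous mediator and outcome; no interactions,
  no binary traits, no multiple mediators.
- The synthetic generator's covariate and cluster models are intentionally
  simple placeholders; conclusions about real cohorts require real data.
- The "presence in pooled panel" criterion is a user-supplied boolean, not
  an array-membership computation.
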