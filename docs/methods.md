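# Methods

This note documents the models, estimators, numerical choices and known
limitations of `adheregx`, and what the synthetic-data generator does and
does not emulate.

## Adherence phenotyping

Two standard pharmacy-claims metrics are computed per patient over a
half-open observation window `[0, 365)` of 0-based day indices, each fill
covering `[fill_day, fill_day + days_supply)`:

* **PDC** counts distinct covered days.  The default *shift-forward* policy
  queues an early refill's supply to begin when the current supply runs out
  (the standard PDC convention); a pure *union* policy is available.  The
  denominator is anchored at the first in-window fill by default — the MPR
  definition anchors at the first dispensing date, and symmetric anchoring
  avoids penalizing late entry — with a window-start option.
* **MPR** divides summed days of supply by the span from first fill to the
  end of the last refill's supply.  Early refills can push it above 1; it is
  capped at 1.0 for classification (oversupply is not better adherence) and
  the raw value is retained.  Both numerator supply and the denominator are
  truncated at the window end; an uncapped/untruncated variant is a flag.

Non-adherence is strictly `metric < 0.80`: a patient at exactly 80% is
adherent.  All medication classes are pooled into one coverage stream per
patient by default (one MPR and one PDC per patient); per-class computation
is a flag.  Patients with no in-window fill have no defined phenotype and
are excluded with a log entry.  Display percentages round half away from
zero; one decimal is kept internally.

## Genotype QC and PCA

QC defaults are the conventional ones: MAF ≥ 0.01, SNP missingness ≤ 0.05,
sample missingness ≤ 0.05, Hardy–Weinberg exact-test p ≥ 10⁻⁶ (computed in
controls when labels are supplied, since case-only disequilibrium can be
signal).  Filters apply in the order SNP call-rate → sample call-rate →
MAF → HWE, each on the current dataset, and the report's removal counts
reconcile exactly with input and output dimensions.

The HWE exact test enumerates heterozygote counts conditional on allele
counts in log space (gammaln), summing configurations no more probable than
the observed one.

PCA standardizes dosages to `(x − 2p̂)/√(2p̂(1−p̂))` after per-SNP mean
imputation of missing calls (imputation is for PCA only; association uses
complete cases per SNP), excludes zero-variance columns with a warning, and
takes the thin SVD.  Scores are `U_k S_k`; eigenvalues `S²/(n−1)`,
non-increasing.  Sign is fixed by making each component's
largest-magnitude loading positive.  Four PCs are used as association
covariates by default; no Tracy–Widom screening is applied.

## Association scan

Each SNP is tested by maximum-likelihood logistic regression (IRLS via
statsmodels GLM) of the binary label on minor-allele dosage plus intercept,
age, sex and PCs.  Inference is Wald: `OR = exp(β)` with
`CI = exp(β ∓ 1.96·se)`, so the geometric mean of the CI bounds equals the
OR — an invariant asserted in tests.  Fits with `|β| > 15` or non-finite
standard errors are flagged as (quasi-)separated rather than silently
reported.  Missing dosages are dropped per SNP (`n_used` recorded).
Covariate designs with condition number above 10¹² are rejected by name.

**Permutation.**  Phenotype labels are permuted as a unit against the fixed
genotype and covariate rows, which preserves LD between SNPs exactly and
also breaks any label–covariate association (documented; a Freedman–Lane
residual-permutation mode is a known alternative and is out of scope).  For
throughput the permutation statistic is the efficient score
`T = U²/V`, `U = g'(y − p̂₀)`,
`V = g'Wg − g'WX(X'WX)⁻¹X'Wg` with the covariate-only null model refit per
permutation — asymptotically equivalent to the Wald test and vectorizable
across all SNPs at once.  Empirical p uses the add-one estimator
`(1 + #{T_perm ≥ T_obs})/(1 + B)` so no p-value is exactly zero; the max-T
family-wise p is returned alongside.  Missing dosages are mean-imputed for
this stage only.

Bonferroni correction is `min(1, m·p)`; `m` defaults to the number of
scanned SNPs and can be fixed to an explicitly analyzed coding subset.
LD-proxy intervals use composite-genotype r² (squared Pearson correlation
of dosage vectors) against all same-chromosome SNPs within ±100 kb and span
the positions of those with r² ≥ 0.5, the index always included.

## GREML

The GRM uses sample allele frequencies, the standardized cross-product for
off-diagonals and the standard within-individual estimator
`1 + (1/m)Σ [x² − (1+2p)x + 2p²]/(2p(1−p))` for the diagonal; missing
genotypes are skipped with per-pair SNP counts.  (The two estimators
coincide exactly only at p = 1/2, which is why the duplicate-pair identity
test constructs a p = 1/2 panel.)

**Relatedness pruning.**  Pairs above a cutoff are pruned greedily,
removing the sample in the most offending pairs until none remains — the
retained set is deterministic and within one of the exhaustive maximum
independent set on small instances.  The conventional cutoff is 0.025, but
that figure presumes genome-wide marker counts: an unrelated pair's
estimated relatedness has sd ≈ 1/√m_eff (LD reduces m_eff below the SNP
count), which dwarfs 0.025 on panels of a few thousand SNPs.
`suggest_prune_cutoff` therefore returns
`max(0.025, 4·sd(off-diagonals))`, and the pipeline uses it when no
explicit cutoff is configured.

**REML.**  The single-GRM model `y = Xb + g + e`, `g ~ (0, A·σ²_g)`,
`e ~ (0, I·σ²_e)` is fit by average-information REML in the eigenbasis of
A (one symmetric eigendecomposition; every iteration is then O(n·c)).
Four EM warm-up iterations precede AI steps; any step that decreases the
restricted likelihood is halved up to 20 times and otherwise rejected, so
the accepted likelihood sequence is non-decreasing.  Components are clamped
at 10⁻⁸·Vp; convergence is |ΔlogL| < 10⁻⁸ within 100 iterations
(GCTA-like defaults).  `Vp = V(G) + V(e)` holds identically by
construction.  SEs come from the inverse AI matrix, `SE(h²)` by the delta
method.  The test of `σ²_g = 0` is a likelihood-ratio test against the
covariate-only model (closed-form REML residual variance) referred to the
50:50 `χ²₀:χ²₁` boundary mixture, so `p = ½·P(χ²₁ > LRT)` and p = 0.5 at
LRT = 0.

The binary trait is analyzed as 0/1, so `V(G)/Vp` is **observed-scale**
heritability.  The Dempster–Lerner/Robertson transformation
`h²_liab = h²_obs·K(1−K)/φ(t)²`, `t = Φ⁻¹(1−K)`, and its inverse are
provided; the observed scale is the primary output.  An identity GRM makes
the two components unidentifiable and is rejected with a clear error.

A scale fact worth knowing: for an unrelated cohort
`SE(h²_obs) ≈ √(2m_eff)/n` — *denser* panels give noisier GRMs less
contrast and hence larger SEs.  At n = 230 with a 5,000-SNP panel the SE
exceeds 0.4, reproducing the regime where a substantial heritability
estimate is statistically non-significant; small panels (m ≈ 2,000) at the
same n give SE ≈ 0.27 and can look spuriously precise relative to a
genome-wide study.

## Power

Under Hardy–Weinberg genotype frequencies and penetrances proportional to
`(1, r, r²)` scaled to the prevalence K, the case and control risk-allele
frequencies are computed exactly, and power is that of the two-sided
two-proportion z-test on allele counts,
`Φ(Δ/SE − z_{1−α/2}) + Φ(−Δ/SE − z_{1−α/2})`, which returns exactly α at
r = 1.  The model caps feasible r where the homozygote penetrance would
exceed 1 — at 67% prevalence the risk direction saturates near r ≈ 1.28,
so `effect_for_power` solves in either direction and high power targets at
high prevalence are typically only reachable with protective effects.
The calculator ships no assumed effect size; the solver exists precisely to
back out what effect a reported power figure implies.

## Pathway protection:risk

SNPs passing p < 0.05 are mapped to genes; each gene's direction comes from
its most significant SNP (ties broken by smaller |log OR|, then SNP id —
the least arbitrary single rule; the choice is logged per gene), OR < 1
protective, OR > 1 risk, OR = 1 no direction.  The pathway P:R ratio is
`n_protective / n_risk` with an explicit ∞ when no risk gene is present
(sorted above all finite ratios) and an undefined marker when no member
gene has a direction.  Labels use strict thresholds: protective iff
P:R > 1.5, risk iff P:R < 0.5; the ratio itself is always reported so
users can apply their own cutoff.  Reciprocal-OR involution (every ratio
maps to its inverse, counts swap) is asserted exactly in tests.

The hypergeometric over-representation p-value is a generic stand-in for
proprietary knowledge-base enrichment engines: pathway definitions must be
user-supplied GMT, and the p-values are not comparable to any such engine's
output.

## Synthetic cohort generator

The generator defines the study conditions the package is exercised under;
its defaults are fixed, not tuned:

* **Cohort**: 230 patients, 365-day window, adherent fraction 0.335 (so
  ~66.5% non-adherent), ages uniform on 43–99, P(male) = 0.38.
* **Dispensing**: every patient fills at day 0.  Adherent archetypes refill
  with gaps Normal(supply, 0.07·supply); non-adherent archetypes with gaps
  Normal(1.7·supply, 0.35·supply) and a 4% per-fill chance of stopping.
  These gap parameters are free choices (no public per-fill data exists to
  calibrate them); they are set so archetypes map onto the PDC80 cutoff
  with ~99% fidelity, making the configured adherent fraction the expected
  prevalence.
* **Genotypes**: per-LD-block ancestral MAF uniform on [0.05, 0.5] (tightly
  linked variants share allele frequency); within a block adjacent SNPs
  share a latent uniform with probability 0.9, giving r² ≈ 0.8 between
  neighbours decaying along the block while preserving marginals;
  haplotypes are sampled independently per individual so genotypes are in
  HWE within subpopulation; optional two-subpopulation structure uses the
  Balding–Nichols beta model at a given Fst.
* **Phenotype**: liability threshold — the standardized causal-genotype
  score is scaled to variance h²_liab, Normal noise of variance 1 − h²_liab
  is added, and labels are liability above the empirical prevalence
  quantile.  Planting an observed-scale target uses the inverse Robertson
  transformation.  In the integrated cohort the liability labels *are* the
  dispensing archetypes, so adherence phenotypes recovered from refill
  records carry the planted genetic signal end-to-end.
* **Seeding**: one global seed spawns independent child streams
  (dispensing, genotypes, phenotype, covariates, gene sets), so stages
  re-run independently and fixture files are byte-identical across runs.

What it does **not** emulate: EHR/ICD cohort extraction, insurance-key
refill capture, real minor-allele spectra and LD decay (no coalescent
simulation), genotyping/sequencing error, relatedness structure, secular
trends in refill behaviour, and any correlation between covariates and
adherence beyond chance.  Passing tests therefore demonstrate the
estimators' statistical correctness under a clean generative model, not
robustness to real-data artifacts.

## Problem sizes used in the checks

The calibration and recovery suites run at desk scale, chosen to bound the
Monte-Carlo error of each check rather than to mimic the study: null-scan
calibration at n = 2,000 × m = 1,000 (type-I error against exact binomial
bounds; permutation p uniformity by KS at B = 1,000); GREML recovery at
n = 1,000 × m = 2,000 over 20 seeds with a ±0.1 bound on mean bias;
the study-scale regime at n = 230 × m = 5,000; metric oracles on 1,000
random record sets; GRM brute force on 20 × 50 panels.  The acceptance
script runs the full pipeline at the 230-patient study scale with 2,000
SNPs and 1,000 permutations.

## Known limitations

* Wald inference only (no likelihood-ratio or exact logistic tests);
  separation is flagged, not resolved (no Firth correction).
* Single-component GREML; no partitioned or bivariate models, no
  mixed-model association.
* The score-statistic permutation is asymptotically, not exactly,
  equivalent to permuting the Wald statistic.
* The LD model is a block-copy construction with tunable within-block r²;
  between-block independence is exact, unlike real genomes.
* Observed-scale h² of an all-SNPs-causal panel matches the Robertson
  expectation only to first order; the recovery test's ±0.1 band absorbs
  the higher-order gap.
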