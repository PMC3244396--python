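# Methods

## The model

`lcgwas` analyses a case-control sample in two stages.

**Stage 1 — latent class analysis.**  For each case, `J = 10` binary
lifetime indicators (substance abuse, OCD, panic disorder, social/specific
phobia, eating disorder, ADHD, alcohol abuse, alcohol dependence, nicotine
dependence, psychotic symptoms) are modelled as a mixture over an
unobserved class variable with `K` levels.  Conditional on class `k`, the
items are independent Bernoulli draws with endorsement probabilities
`ρ_kj`; the class prior is `π`.  The per-case likelihood is the mixture sum
over classes.  Missing indicator entries are assumed missing at random and
drop out of the per-case product item-wise, so all available observations
contribute.  Controls carry no indicator data and never enter the class
model.

**Stage 2 — association.**  The phenotype for class `k` assigns each case
its posterior membership probability `P(c = k | u)` and each control 0 (a
0/1 modal-class indicator is available as an alternative definition).  One
genome-wide scan is run per latent class.  Each SNP is recoded under the
dominant (carrier), additive (dosage) and recessive (homozygote) models of
the minor allele and tested with a correlation trend test: `T = n·r²`
against a 1-df chi-square, where `r` is the Pearson correlation between
encoded genotype and phenotype over complete pairs.

## Estimation choices

* **EM.**  E-step by Bayes rule; M-step is posterior-weighted item means
  with missing entries excluded item-wise.  Identical response patterns are
  collapsed with multiplicities before the loop, which leaves the
  likelihood unchanged and bounds the E-step by the number of distinct
  patterns (≤ 2^J) rather than the sample size.
* **Starts.**  `ρ ~ Uniform(0.1, 0.9)`, `π ~ Dirichlet(1)`.  Default 50
  random starts in tests and the acceptance script; 1000 mirrors the
  original analysis and is a parameter.  Seeds derive from one
  `SeedSequence`, and the winning start index is recorded.
* **Convergence.**  Absolute log-likelihood gain < 1e-8, at most 1000
  iterations.  EM can crawl (gain just above tolerance for hundreds of
  iterations) near weakly identified directions; such runs are flagged
  `converged=False` but still usable — all starts typically agree on the
  maximum to ~1e-4.
* **Boundary handling.**  During EM, `ρ` is clipped to `[1e-6, 1 − 1e-6]`
  so the log-likelihood stays finite; the reported estimates are the
  unsmoothed M-step values, snapped to exact 0/1 when within 1e-6 of the
  boundary (boundary solutions such as a class that never endorses alcohol
  dependence are genuine and printed as 0 and 1).
* **Label switching.**  Classes are canonicalised by descending endorsement
  of an anchor item (default: alcohol dependence), falling back to
  descending `π`.  This keeps class identities stable across seeds and
  replicates.
* **Model selection.**  `K` minimising `BIC = −2·logL + p·ln n` with
  `p = (K − 1) + K·J`.  Class separation is reported as relative entropy
  `1 − Σ(−p ln p)/(n ln K)`; 1 is crisp, 0 uninformative.  `K = 1` has a
  closed-form MLE and is fit in one start.
* **Profile odds ratios.**  `OR_j = odds_k(j) / odds_l(j)` between two
  classes.  Items whose `ρ` is within 1e-6 of 0 or 1 in either class are
  reported not-available (the odds are undefined at the boundary).
  Standard errors use the delta method with `var(logit ρ_kj) =
  1 / (n_kj^eff ρ(1−ρ))`, where the effective count is the posterior mass
  of class `k` over cases observed on item `j`; this is the inverse
  observed information of the weighted Bernoulli problem.  The SEs describe
  estimation uncertainty conditional on the class structure and are not
  calibrated against any external target.
* **Auxiliary variables (pseudo-class Wald test).**  Covariates never enter
  the likelihood.  For each of `D = 20` draws, a class is sampled per case
  from its posterior row; per-draw class means and squared standard errors
  of the covariate are pooled multiple-imputation style (total variance =
  mean within-draw variance + `(1 + 1/D)` × between-draw variance), and
  equality of the `K` pooled means is tested with a Wald chi-square on
  `K − 1` df.  Note the attenuation property: pseudo-class draws shrink
  observed between-class mean differences roughly by the assignment
  accuracy, so at relative entropy ~0.7 a 3-year age contrast with SD ~13
  is recovered only partially and the global test has modest power at
  n = 1000.  The ordinal pattern (which class is oldest) is robust.

## Association details

* **Minor-allele orientation** is recomputed on the combined case-control
  sample before any test; SNPs with counted-allele frequency > 0.5 are
  flipped and logged.
* **MAF filter** removes SNPs with MAF strictly below the threshold
  (default 0.001); the boundary survives.  Removed and kept counts are
  logged and conserved.
* **Testability.**  A SNP×model combination with fewer than two distinct
  encoded values or phenotype values among complete pairs is not testable
  — in particular a recessive test with zero minor-allele homozygotes —
  and is excluded from the Bonferroni count rather than given a spurious p.
* **Stratification correction.**  Genotypes are standardised per SNP
  (centre `2p̂`, scale `sqrt(2p̂(1−p̂))`, missing → mean), monomorphic SNPs
  skipped; the leading left singular vectors of the standardised matrix are
  the component scores.  Both encoded genotype and phenotype are
  residualised on the scores (least squares with intercept) and
  `T = (n − K_pc − 1)·r²` on the residuals.  The number of components
  defaults to 10 and is configurable; with no structure simulated the
  pipeline examples use 0.  Correction restores the genomic inflation
  factor λ (median χ² / 0.4549) to ≈ 1 under strong simulated confounding.
* **Multiplicity.**  Bonferroni per genetic model over the testable SNPs of
  that model (`min(1, p·m)`); the three models are not pooled.  SNPs whose
  Bonferroni p is ≤ α (default 0.05) are retested with `B` phenotype
  permutations (default 1000), `p = (1 + #{T_perm ≥ T_obs}) / (B + 1)`,
  which floors at 1/(B+1).  When components are in play, residuals are
  permuted.
* **Hardy–Weinberg exact test** (optional post-hoc filter, off by default):
  full enumeration of heterozygote counts given the allele counts, summing
  configurations no more probable than the observed one.

## The synthetic cohort generator

The generator emulates the design of a bipolar-disorder GWAS cohort and is
the test bed for every downstream stage.  Defaults are the study
conditions:

* 1000 cases / 1034 controls; three classes at proportions
  (0.26, 0.25, 0.49); the 10×3 endorsement matrix of the published class
  profiles (substance-abuse/psychosis class, alcohol-dependence class with
  endorsement 1.0 of alcohol dependence, low-co-morbidity class).
* Ages normal per class (means 41/41/44, SDs 12.6/10.8/13.8 years),
  truncated at 17 (the youngest case age); controls a single stratum
  (mean 52.5, SD 17.6, truncated at 18).  Female probabilities
  0.62/0.39/0.49 per class, 0.486 for controls.  Case ages go missing at
  rate 0.008 (~8 of 1000).
* Genotypes: null SNPs in Hardy–Weinberg proportions at MAFs uniform on
  (0.01, 0.5); with `fst > 0`, Balding–Nichols subpopulation frequencies
  (`Beta(p(1−F)/F, (1−p)(1−F)/F)`) with a 50/50 population split
  independent of case status, so the uncorrected scan is confounded only
  when the phenotype is made ancestry-dependent.  Genotype calls go missing
  at rate 0.005 by default, reflecting a high post-QC array call rate.
* Planted effects: three recessive variants whose minor-allele homozygotes
  are confined to one class — two rare ones (MAF 0.06 and 0.03, four
  homozygotes each) targeting the substance-abuse/psychosis class and one
  commoner one (MAF 0.15, 46 homozygotes) targeting the
  alcohol-dependence class.  Effects are planted by overwriting the
  genotypes of randomly chosen members of the target class rather than
  through a penetrance model: for recessive effects, chance homozygotes
  from the null draw are first demoted to heterozygous, so the homozygote
  count is exact, confined, and auditable from the truth record.  Forced
  entries are never masked by the missingness process.  For
  dominant/additive effects the chosen carriers are set to the risk
  genotype but naturally drawn carriers elsewhere are left alone (demoting
  them would destroy the MAF), so exactness of the carrier count is a
  recessive-model guarantee.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, intensity-level genotyping error, sex chromosomes,
age/ancestry correlations, or indicator missingness.  Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to array artefacts or LD-induced
dependence between tests.

## Problem sizes used in the shipped checks

The test suite and acceptance script scale the simulations to what the
statistics need rather than to the full 728k-SNP panel: latent-class
refits use 1000 cases with 50 EM starts averaged over 10 seeds; model
selection runs K = 1..5 over 10 replicates; calibration checks use 10⁴
permutation replicates and 10⁴-SNP panels (where the sampling noise of a
median-based λ is ±0.02); end-to-end scans use 2000–5000 null SNPs.  The
Bonferroni arithmetic of the original panel size is checked in closed form.

## Known limitations

* The χ²₁ reference for `T = n·r²` is anticonservative in the far tail for
  the recessive encoding of rare SNPs (a handful of homozygotes) against a
  zero-inflated phenotype; occasional null SNPs can reach Bonferroni-level
  p in a genome scan.  This mirrors the behaviour of trend tests on tiny
  cells generally; such hits are exactly what the permutation retest and
  manual review step exist for, and the permutation p floors at 1/(B+1),
  so at B = 1000 it cannot confirm genome-wide-level claims, only screen
  out fragile ones.
* Reported Bonferroni values follow `min(1, p·m)` with `m` the testable-SNP
  count of the model; documented source tables that round differently
  (e.g. a printed 0.01 where `p·m` gives 0.012) are matched only to their
  printed precision.
* The pseudo-class Wald test attenuates true covariate contrasts (see
  above); with auxiliary effects of a few tenths of a standard deviation
  it should be read as conservative.
* BIC selection at n in the low hundreds is conservative and may merge the
  two high-co-morbidity classes; the shipped pipeline tests use n ≥ 500.
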