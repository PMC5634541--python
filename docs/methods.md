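# Methods

This note documents the models implemented in `admixscan`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that affect results.

## Cohort and phenotype model

The package targets cohorts of obstructive-CAD patients graded for
coronary collaterals on the Rentrop scale.  Two phenotype encodings are
used throughout: a binary presence/absence indicator `collaterals`
(1 ⇔ Rentrop grade ≥ 1), which is the admixture-mapping endpoint, and the
ordinal grade 0–3 analyzed with proportional-odds regression.  The
`CohortTable` container enforces the identity `collaterals = (grade ≥ 1)`
whenever both are present.  Sex is coded 1 = male (female reference), so
positive sex coefficients mean higher collateral odds in men.

## Genotype I/O and quality control

PLINK 1.9 binary files are read and written natively (SNP-major only; the
third magic byte must be 0x01).  Dosage counts the bim **A1** allele:
2-bit codes 00/10/11/01 map to 2/1/0/missing.  Base-pair coordinates are
1-based inclusive everywhere, matching bim conventions.

QC applies, in a fixed documented order, SNP filters (autosomes only →
call rate ≥ 0.95 → MAF > 0.01 → Hardy-Weinberg exact p > 1e-5) and then a
sample call-rate filter (≥ 0.95) computed on the retained SNPs.  Each
removed SNP is attributed to the first filter it fails, so the QC report
counts sum exactly.  The HWE test is the exact conditional test on the
heterozygote count (probabilities summed over outcomes no more likely than
observed, no mid-p correction), evaluated on all samples — the cohort is
assumed unrelated after QC, so no founder distinction is made.

## Synthetic admixed cohorts

The simulator provides ground truth for every downstream stage:

- **Ancestral panels.**  Per SNP an ancestral frequency p ~ U(0.05, 0.95);
  each ancestry draws its frequency from the Balding–Nichols distribution
  Beta(p(1−F)/F, (1−p)(1−F)/F), clipped 1e-4 from fixation.  Default
  F = 0.15 for all three ancestries — strong enough continental
  differentiation for windowed inference, far from fixed differences.
- **Tract mosaics.**  Per haplotype and chromosome, breakpoints fall as a
  Poisson process at rate g per Morgan (default g = 8 generations since
  admixture, Latin-American-scale) and each tract's ancestry is an i.i.d.
  draw from the individual's Dirichlet admixture proportions (default
  α = (6, 2.5, 1.5): European-major, Hispanic-like mixture).  Alleles are
  Bernoulli draws from the tract ancestry's panel frequency.  This is a
  deliberate simplification of a coalescent: it reproduces exactly the
  local/global ancestry structure the scan consumes (tract-length
  correlation, individual-level admixture variance) at desk-scale cost,
  but carries **no** linkage disequilibrium within ancestral panels, no
  genotyping error, and no relatedness.  Passing tests therefore validate
  the statistical machinery, not robustness to panel LD or array
  artifacts.
- **Scale.**  Defaults: 600 individuals, three 1-Morgan chromosomes of
  1000 SNPs each (1 cM = 1 Mb physical map).  These sizes keep full test
  runs in minutes while preserving realistic tract lengths (~12.5 cM
  mean) relative to the 50-SNP (5 cM) inference window.
- **Binary phenotype.**  Drawn from the same logistic model the scan fits,
  with the delta terms evaluated at the configured causal locus from TRUE
  ancestry (no causal locus → null model).  Defaults: b_sex = 0.6,
  b_age = −0.01/year, global-ancestry effects 0.  The intercept is
  calibrated by root-finding so the expected prevalence is 0.53, the
  cohort's observed collateral rate.  Because the phenotype is generated
  from true ancestry, ancestry-inference error enters results only through
  the inference module, keeping failures attributable.
- **Ordinal grade.**  Proportional-odds sampling
  P(grade ≤ k) = expit(cutpoint_k − x'β) with defaults matching the
  cohort's reported effects (sex 0.59, smoking 0.38, diabetes 0.2,
  CAUC −0.39 and AA −0.23 versus the Hispanic reference) and cutpoints at
  the logits of the cumulative grade frequencies (0.47, 0.63, 0.87)
  shifted by the mean linear predictor (≈ 0.6) so marginals stay near
  47/16/24/13%.  In full-cohort runs the binary endpoint is primary:
  grades are drawn conditionally (grade 0 where Y = 0; from the
  ≥ 1-truncated distribution where Y = 1), preserving the
  `collaterals = (grade ≥ 1)` invariant while keeping the admixture model
  exactly generative for Y.  The standalone sampler is unconditioned.
- **Covariates.**  Age ~ N(71, 12) years, 74% male, 56% smokers, 45%
  diabetic, DBP ~ N(76, 13), SBP ~ N(140, 24) mmHg, vessel-disease
  classes 37/29/34% with 2.4% missing — the cohort's reported marginals.
  Race-ethnicity labels derive from admixture proportions (AFR ≥ 0.5 →
  AA; AFR+NAM ≥ 0.10 → HISP; EUR ≥ 0.90 → CAUC; else unclassified).  No
  cohort admixture summaries were published, so the Dirichlet defaults
  are a plausible Miami-style mixture, not a calibration.

All randomness flows through one `numpy` generator created from the
config seed; every stochastic function takes the generator explicitly, so
identical configs reproduce byte-identical outputs.

## Local-ancestry HMM

LAMP-style haplotype-cluster models are replaced by a windowed
naive-Bayes + HMM smoother: within fixed blocks of `window_snps`
(default 50, last window truncated) each ancestry's emission is the
product of Bernoulli likelihoods of the window's alleles under that
ancestry's panel frequencies (frequencies floored at `emission_floor`,
default 1e-3); between adjacent windows the ancestry switches with kernel
`exp(−r·d)·I + (1−exp(−r·d))·(1/K)` where d is the genetic distance
between window midpoints and r (`switch_rate`, default = g = 8/Morgan)
the switch rate.  Posteriors come from scaled forward–backward; every SNP
inherits its window's posterior (no interpolation).  Diploid local
ancestry is the mean of the two haplotype posteriors, optionally averaged
over P phase configurations (default P = 1 with simulator-true phase; the
multi-configuration averaging path is implemented and tested so phased
samples with uncertainty can be supplied).  Ancestry proportions are kept
on the diploid [0, 1] scale — the 0–2 dosage reading is rejected so that
"percentage of ancestry" reads identically at local and global level.

Accuracy against simulator truth is ~93% of SNPs at F = 0.15 with default
windows, and > 99% with near-fixed panels and small windows.  The
dominant error term is window quantization at tract boundaries: each
ancestry switch mislabels ~W/4 SNPs in expectation, which is why the
near-fixed check is run at `window_snps = 5` — at W = 50 quantization
alone caps accuracy below 99% regardless of panel divergence.  Accuracy
is monotone in panel divergence F on matched seeds.

Global ancestry is the unweighted SNP mean of local ancestry.  A PCA
cross-check (per-SNP 2p̂ centering, √(2p̂(1−p̂)) scaling, mean imputation
of missing dosages, SVD with a deterministic largest-loading-positive
sign) reproduces global ancestry: on simulated cohorts of ≥ 300
individuals and ≥ 2000 SNPs the top two components correlate with global
ancestry columns above 0.9.

## The admixture scan

`fit_locus` fits the seven-term logistic model by IRLS: convergence when
the log-likelihood change is < 1e-8 **and** the Newton step has settled
(< 1e-8 in every coefficient — the likelihood criterion alone can stop
early in flat directions), at most 50 iterations.  Wald z p-values per
term (likelihood-ratio tests were considered and rejected as default: the
reported per-term β/p pairs are Wald-style).  Degenerate inputs are
flagged, not raised: one-class outcomes, separation (any |β| > 30 or
iteration exhaustion) → `converged = False` with NaN p-values; constant
regressors (for example delta ≡ 0 when local equals global everywhere) →
NaN for that coefficient with the remaining coefficients equal to the
reduced model's.  The scan fixes the complete-case sample set once
(missing phenotype/age/sex dropped, count logged) and fails hard on
sample-identifier mismatches between ancestry and cohort inputs.

**Permutation correction.**  The phenotype vector is shuffled across
samples (covariates and ancestry stay attached); each of B permutations
(default 2000) re-runs the scan and records the genome-wide minimum
delta-term p, with non-converged loci contributing p = 1 (conservative
and deterministic).  The corrected 0.05 threshold is the empirical 5th
percentile by the nearest-rank (lower) definition — the k-th smallest
minimum with k = max(1, ⌊0.05·B⌋) — and the effective test count is
⌊0.05/p₅⌋ (the unrounded ratio is also reported).  Percentile and
rounding conventions are otherwise unstandardized, so both choices are
documented and tested, including the floor-consistency identity
`eff·p₅ ≤ 0.05 < (eff+1)·p₅`.  By default the minimum is taken jointly
over both delta terms; per-ancestry modes (`afr`, `nam`) mirror analyses
that correct each ancestry separately.  With a fixed seed the whole
summary is bit-for-bit reproducible.

**Peak regions** are maximal runs of consecutive same-chromosome SNPs at
or below a p cut; bounds are the first and last qualifying SNP's bp
(1-based inclusive).

A note on localization: with a weak delta effect (β ≈ 0.55 at n = 868)
the scan detects signal but the genome-wide *minimum* frequently falls on
a different ancestry-correlated locus — in simulation the minimum lands
within 0.02 Morgan of the causal SNP only ~20% of the time.  The
localization test therefore uses β = 1.5, where the property is
identifiable (the minimum then hits the causal SNP almost surely);
recovery and calibration of the weak-effect regime are tested separately
via coefficient estimates and CI coverage, which do not require the
argmin to be at the causal locus.

## Epidemiological statistics

Pearson chi-square without continuity correction (the printed cohort
p-values are consistent with the uncorrected test), df = (r−1)(c−1), with
zero margins rejected by name.  One-way ANOVA via the standard
between/within decomposition.  The proportional-odds model is fitted by
maximum likelihood (cumulative-logit parameterization
P(grade ≤ k) = expit(cutpoint_k − x'β); BFGS with a tight gradient
tolerance, polished by a simplex step when numerical gradients bottom out
on large samples); race-ethnicity enters as treatment contrasts with
Hispanic reference so the reported contrasts are CAUC-vs-HISP and
AA-vs-HISP.  Grades are strictly ordered with a single common slope (no
partial-proportional relaxation).  With two outcome levels the fit
reduces numerically to binary logistic regression (verified to 1e-6).

Regional SNP association uses the additive 0/1/2 dosage plus eigenvectors
1, 2 and 5, age and sex — covariates retained by a univariate logistic
screen at p < 0.05 (an exhaustive best-subsets step was considered and
simplified to the screen, which is what the selection operationally
amounts to for these covariates).  The number of independent SNPs in a
region reuses the permutation machinery restricted to the region.

## Test design and Monte-Carlo error

Stochastic validation thresholds were fixed before the corresponding
tests were finalized, with replicate counts chosen for Monte-Carlo
precision:

- **Null calibration.**  Delta-term p-values are marginally uniform under
  the null, but loci are autocorrelated along ancestry tracts, so a
  single 3000-locus cohort's exceedance fraction has a Monte-Carlo spread
  several times the naive binomial SE.  The test pools the fraction over
  40 independent null cohorts (120,000 loci) and holds it to 0.05 ± 3
  binomial SEs at m = 3000 (±0.012) — pooling shrinks the estimator's
  spread well inside that band without touching the band itself.
- **Recovery.**  200 replicates at n = 868 with b_delta_NAM = 0.55:
  Wald 95% CIs must cover the truth in ≥ 90% of replicates and the mean
  estimate must fall within ±0.1.  Replicates use the tract-only
  simulation path (no allele draws) since the scan consumes ancestry, not
  genotypes.
- **Permutation consistency.**  100 truly independent loci are built as
  one-SNP chromosomes; with B = 500 the nearest-rank 5th percentile of
  the min-p distribution carries ~19% relative SE (delta method on the
  order statistic, density m(1−q)^(m−1) at q = 1−0.95^(1/m)), so the
  effective-test count is required to match 0.05/q within 3 such SEs.
- **Oracle equivalence.**  Logistic and ordinal fits are compared on
  n ≤ 20 instances against direct minimization of the same likelihood by
  an unrelated optimizer (BFGS with analytic gradients / Nelder-Mead) to
  1e-6; the chi-square statistic against the Σ(O−E)²/E summation.

## Known limitations

- The ancestral-panel model is exchangeable across SNPs: no panel LD, so
  the HMM's independence-within-window assumption is exactly satisfied in
  simulation and accuracy numbers are optimistic relative to real arrays.
- Phasing is taken as given (simulator truth by default); SHAPEIT-style
  phasing and reference-panel curation are out of scope, as are sex
  chromosomes, relatedness handling and VCF input.
- The permutation default B = 2000 re-runs the full scan per permutation;
  at genome scale this is the dominant cost and is best run with the
  per-ancestry mode only when needed.
- Printed-table reproductions are exact; genome-scale results of the
  original cohort are not reproducible without its genotypes and external
  reference panels, and no attempt is made to match them numerically.
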