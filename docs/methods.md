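# Methods

This note records the models, defaults, and numerical choices behind
`erpmed`, and what the synthetic-data tests do and do not establish.

## Synthetic cohort generator

The generator (`erpmed.simulate`) emulates a case–control psychosis cohort:
383 subjects whose diagnosis mix (≈136 SCZ / 122 BPD / 125 controls) arises
from cluster-conditional multinomial draws, six ERP summary measures from a
latent three-component Gaussian mixture, and genotypes/discovery GWAS with a
configurable causal link from a true polygenic score to membership in the
impaired mixture component.

**Genotypes.** Haplotypes are Gaussian-copula draws: within each contiguous
LD block of `ld_block_size` variants (default 50) the latent normals follow
an AR(1) process with lag-one correlation `within_block_r` (default 0.8);
blocks are independent. An allele is the latent normal thresholded at the
MAF quantile (MAF ~ U(0.05, 0.5)), and a genotype is the sum of two
independent haplotypes, so Hardy–Weinberg equilibrium holds by construction.
This gives simple, controllable LD; it does not reproduce human LD maps
(recombination hotspots, allele-frequency/LD coupling), which is deliberate —
stages that consume LD (clumping, pruning, relatedness) only need *known*
correlation structure. Default panel size is 100,000 variants spread over 22
autosomes at 5 kb spacing; tests and the acceptance script run scaled-down
panels (400–20,000 variants) because every property checked is
size-independent.

**Discovery GWAS.** Per trait, `n_causal` variants (default
`min(500, m/10)`) receive normal effects with SD 0.05; reported effects add
noise at `se = 1/sqrt(2 N p (1-p))` for the trait's effective discovery size
(defaults on the order of the real consortium studies: SCZ ≈ 77k,
BPD ≈ 17k, college ≈ 101k, childhood intelligence ≈ 12k), and p-values are
two-sided normal tails. Null p-values are therefore exactly uniform, and the
reported/true effect correlation grows with discovery size — both are tested.

**ERP mixture.** Per-cluster means/SDs for the six measures are free
parameters of the generator (no published per-cluster table exists to copy).
Defaults were chosen once so that the three clusters are *distinct* in the
sense the study describes — adjacent clusters separated by ≈2 within-cluster
SDs per measure — which makes the latent structure recoverable (V-fold
selection of k=3, label agreement ≥ 0.95) and places the impaired cluster
strictly worse on all six measures: higher P50 ratio, smaller S1/|N1|/P2/P3
amplitudes, longer P3 latency. N1 is generated and clustered as a magnitude
(positive µV), so "smaller = worse" applies uniformly to the four
amplitudes; the impairment-direction vector (+1, −1, −1, −1, −1, +1) is
configurable.

**Mediation structure.** A single coefficient set (`MediationTruth`) is the
generating truth for both the mediator model
`logit P(impaired) = b0 + b1·PRS_z + b2'C` (defaults −1.75, 0.5 — giving an
impaired mass of ≈60/383 and an odds ratio of 1.65 per PRS SD) and the
outcome model `PANSS+ = t0 + t1·PRS_z + t2·GI + t3·PRS_z·GI + t4'C + ε`,
ε ~ N(0, 7), defaults (16, 0.5, 4, 0, 0): impaired-cluster membership raises
the positive-symptom score by ~4 points against a residual SD of 7,
matching the observed scale of the phenotype (means ≈20 vs 16, SD ≈7).
`cluster_logit` is kept as an alias for (b0, b1) so cluster-generation code
reads naturally; there is one source of truth. PANSS is produced for cases
only and observed for a random 161/258 of them (missing completely at
random); the chlorpromazine-equivalent dose is lognormal for cases only.
Smoking is cluster-dependent (42% impaired vs 24% not), reproducing the
descriptive-table contrast in expectation.

**Randomness.** One master seed feeds named substreams (variant metadata,
genotypes, per-trait summary statistics, phenotypes), so any stage can be
regenerated independently and identical configs are bit-identical.

## Quality control

Filter order: variant filters (sex chromosomes → call rate < 98% → MAF <
0.05 → HWE exact P < 1e-6), then sample filters (missingness > 5%,
heterozygosity > 3 SD from the mean), then relatedness, then PCA. The HWE
test is the exact conditional test (sum over heterozygote counts no more
probable than observed, enumerated in log space) — appropriate for the
stringent 1e-6 regime where the chi-square approximation is unreliable — and
is applied to all samples (a controls-only flag is not provided because the
generating model is HWE everywhere). Relatedness uses the classic
method-of-moments IBS→IBD decomposition (PI_HAT = Z2 + Z1/2, clamped to
[0, 1]) on a panel LD-pruned at r² < 0.2 in 100-variant windows, without
small-sample correction factors; within a flagged pair the sample with more
missingness is dropped (ties by id). PI_HAT has sampling SD ≈ m^(-1/2), so
a few thousand pruned variants are needed before the 0.125 threshold is
meaningful; the low-confidence warning fires below 50 informative variants.
PCA mean-imputes missing dosages, scales each variant by sqrt(2p(1−p)), and
eigendecomposes the sample Gram matrix (samples ≪ variants); coordinates are
scaled by the square-rooted eigenvalues.

## Clustering and K selection

Measures are z-scored before K-means (they mix %, µV, ms); centroids are
relabeled by ascending norm so labels are sample-order invariant; k-means++
with 50 restarts (10 inside cross-validation, where 40 fits per fold-k pair
would be wasteful).

Choosing K by held-out distortion needs care: the mean squared distance of
held-out points to the nearest trained centroid is *generically decreasing in
K* — splitting even a single multivariate Gaussian buys a real reduction — so
an argmin rule degenerates to the largest K. Measured on a single
6-dimensional Gaussian at these sample sizes, the spurious marginal
improvement per added cluster reaches ~10%; genuine cluster structure in the
generator produces 2→3 drops above 20%. The selection rule therefore grows K
while the marginal relative improvement exceeds `rel_tol` (default 0.12, just
above the measured null ceiling) and stops at the first K whose successor
buys less. On structureless data this returns the smallest candidate.

The globally impaired cluster is the one whose direction-aligned centroid
dominates on all six measures; if no cluster dominates (possible for odd
direction conventions), the largest rank-sum is used and flagged, and an
exact rank-sum tie raises for manual review.

## Scoring and association

Clumping is greedy by ascending discovery P (ties broken by chromosome then
position, for determinism), retaining each surviving variant and removing
neighbors within ±250 kb with target-sample r² > 0.1 (mean-imputed, centered
dosages); the MHC (chr6:26–33 Mb, 1-based inclusive) is removed first.
Strand-ambiguous A/T and C/G variants are dropped during harmonization, and
effects are sign-flipped when the discovery effect allele is the target ref
allele. Missing dosages score as twice the target-sample effect-allele
frequency. Scores are standardized before the logistic fit, so betas are
log-odds per score SD.

The logistic fitter is IRLS (Newton steps, convergence at max coefficient
change < 1e-8, 100-iteration cap) with explicit rank and separation
diagnostics that name the offending column — written in-package both for
those contracts and because the mediation bootstrap refits thousands of
small models; statsmodels serves as the independent oracle in tests, never
as the implementation. The PRS variance explained is reported as the
*incremental* Nagelkerke R²: Nagelkerke(full) − Nagelkerke(PCs only),
floored at 0 (a constant score reports exactly 0). FDR uses
Benjamini–Hochberg across the 20 trait×threshold tests within each subset
(all subjects; cases only) — deterministic, with no π₀ estimation.
Descriptive comparisons use the pooled-variance two-sample t-test and
Pearson chi-square without continuity correction, which reproduce the
published worked examples to printed precision.

## Mediation

Effects are evaluated conditionally at the covariate means of the analysis
subset (the natural-effect formulas are covariate-conditional; the
evaluation point is a reporting choice, exposed as an argument). For linear
outcomes NDE + NIE = total exactly; for binary outcomes the rare-outcome
odds-ratio approximations are used and reported as log-ORs, with the
odds-ratio-scale proportion mediated. The primary correctness oracle —
enforced in tests — is a Monte-Carlo counterfactual simulation E[Y(a, M(a*))]
at 10⁶ draws agreeing within 3 MC standard errors across random coefficient
sets, both families, with and without exposure–mediator interaction.

The bootstrap is bias-corrected percentile (BC, no acceleration): z0 from
the fraction of replicates below the point estimate (clipped to
1/(B+1)), bounds at Φ(2z0 ± 1.96) percentiles, 200 replicates by default;
replicates that fail to fit (separation, constant mediator) are skipped,
with an error above a 20% failure rate. A degenerate statistic collapses to
a point interval. Intervals are produced for NDE, NIE, total, and the
proportion mediated.

The unmeasured-confounding sensitivity analysis augments the data with a
simulated standard-normal confounder U constructed to have target
correlations (r_MU, r_YU) with the mediator and outcome — by solving the
2×2 correlation system in the standardized (M, Y) pair and adding
independent Gaussian residual (infeasible targets raise) — then refits both
models including U and averages the re-estimated effects over 100 seeded
draws. The mediator can enter the construction either as the binary
indicator (point-biserial reading, default) or via a latent logistic
liability draw consistent with the fitted mediator model; both are exposed
because "correlation with the mediator" is ambiguous for a binary M. The
zero-strength grid point returns the unadjusted estimates exactly rather
than a noisy average.

**Recovery design points.** Parameter recovery is exercised at proportions
mediated 0, ≈0.25, and 1. The generating coefficients act on the continuous
PRS while the analysis contrasts quartile extremes of a finite cohort, so
for the interior design point the truth of the quartile-contrast estimand is
computed by running the generator's phenotype model at n = 300,000 and
fitting once (a consistency oracle); at the boundary points the truth is
analytic (t2 = 0 ⟹ PM = 0; t1 = t3 = 0 ⟹ PM = 1). Recovery runs use the
generator's retained latent-truth columns (true PRS, true cluster) so that
what is measured is the mediation machinery against known truth; the full
estimated-PRS / K-means path is exercised separately end to end, where
estimation noise and mediator misclassification attenuate the indirect
effect — as they would in real data.

## What the synthetic tests do not show

The generator's LD, covariate, and noise models are deliberately simple:
passing tests demonstrate the *algorithms* are correct under their stated
assumptions (no unmeasured confounding given the modeled covariates, correct
model forms, MCAR missingness), not that those assumptions hold in any real
cohort, and not that real ERP clusters are as separable as the defaults.
Problem sizes in the test suite and acceptance script (variant panels of
400–20,000; 15 seeds per recovery design point; 50 clustering runs; 20 null
cohorts) are the package's chosen verification scale; all checked properties
are invariant to panel size.
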