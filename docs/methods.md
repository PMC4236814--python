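# Methods

This note documents the statistical procedures implemented in `geqtl`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Gene-based PLS (`geqtl.pls.GeneBlockPLS`)

Both blocks are centered and scaled to unit variance (ddof = 1) with
*training* statistics; this makes SNP blocks (codes 0/1/2) and expression
blocks commensurable and matches the common PLS convention for mixed-scale
predictors.  Factors are extracted by NIPALS in regression mode: the Y-score
proxy is initialized from the largest-variance transcript column
(deterministic), weight/score updates alternate until the X-score changes by
less than `tol` (default 1e-10, relative), and both blocks are deflated on
the X-score — `S <- S - F_S L_S`, `T <- T - F_S (L_F L_T)` — so the model is
a regression of the transcript block on genetic factors, not a symmetric
canonical analysis.  Extraction stops at `n_factors`, at the rank bound
min(s, n-1), or when the residual X-block variation falls below `tol` times
the total.

Numerical conventions:

- **Sign indeterminacy** is fixed by making the largest-magnitude entry of
  each X-weight vector positive, so weights and scores are reproducible
  across platforms and runs.
- **Zero-variance columns** (monomorphic SNPs inside a fold, constant
  probes) are dropped internally with a warning; their coefficient rows are
  zero.
- The coefficient matrix is assembled as `B = W (P'W)^{-1} Q'` in the scaled
  space — the factor-space form of (L_S)^{-1}(L_F L_T) — and `predict`
  wraps it in the centering/scaling transforms.  `predict(..., n_factors=0)`
  returns the training mean of every probe.
- Per-factor explained variation is ||f p'||^2 (resp. ||f q'||^2) over the
  total centered-scaled block sum of squares; the per-factor association is
  the Pearson correlation of the paired scores.  When a pair keeps several
  factors the *first* factor's correlation is reported as the headline
  association and all factors are kept in the model object; no reduction
  across factors is invented.
- The automatic factor cap is min(s, t, n-1, 10).  The cap of 10 keeps the
  7-fold PRESS profile affordable at scan scale; it is a parameter
  (`max_factors_cap`), not a statistical claim.

In the univariate limit (s = t = 1, one factor) the fit reproduces ordinary
least squares exactly; the first factor agrees with an independently
converged reference NIPALS to ~1e-10 (both are pinned to the dominant
singular vector of X'Y).  Note that in a *multivariate* noiseless system the
first-factor score correlation is legitimately below 1 — the first
covariance-maximizing direction is not the full regression fit — so perfect
correlation is only expected with a single SNP.

## Factor-count selection (`geqtl.model_select`)

7-fold cross-validation with **interleaved** fold assignment (sample i in
fold i mod 7) as the default, mirroring the deterministic split convention
of the statistical software this procedure descends from; a seeded-random
scheme is available.  Centering/scaling is recomputed inside every training
fold, so held-out residuals are honest.  For each candidate r (r = 0, the
training-mean model, is always included) PRESS sums squared held-out
residuals over all folds and responses and root mean PRESS is
sqrt(PRESS/(n t)).

Van der Voet's randomization test compares a candidate model's CV squared
residuals with the minimizer's: statistic C = sum of paired differences of
squared residuals; the null flips each cell's difference with probability
1/2 (2000 randomizations by default); the one-sided p is the fraction of
randomized statistics >= the observed.  The selected count is the smallest
r with p >= 0.10 (the conventional default for this test; the minimizer
itself has p = 1 by construction).  Only squared-residual randomization is
implemented; the Hotelling-type approximation variant is not.

If a training fold cannot support the full candidate factor range (rank
deficiency), predictions for the missing counts fall back to the fold's
largest extractable model and the curve is truncated to the range all folds
support.

## eQTL calling (`geqtl.eqtl`)

A pair is recorded when the selected count is >= 1 **and** the refit-on-all-
samples model explains more than epsilon = 1e-8 of each block's variance
("non-zero variation" needs a numerical floor).  CV selects; the reported
model is the refit on all samples.  Cis/trans is gene-id equality.  Missing
genotypes are mean-imputed per column before fitting (call-rate QC bounds
missingness at 10%, where mean imputation is benign).  The scan driver
sorts samples canonically (by id) before fold assignment, so results are
invariant to input row order; per-pair seeds are derived from a CRC of the
gene ids, so results are also invariant to scan order and resumable from a
checkpoint file.  All-pairs scans above 10^4 pairs require an explicit pair
filter: a desk-scale guardrail, since full scans of ~10^4 x 10^4 genes are
cluster-scale by construction.  No multiple-testing control is applied
across pairs at the calling step; users combining scans should adjust
downstream.

## SNP QC and probe selection (`geqtl.preprocess`)

QC removes, in order: non-autosomal SNPs; call rate < 0.9; MAF < 0.01
(computed on non-missing calls; "non-polymorphic" is read as the MAF
threshold); Hardy–Weinberg violations; inter-gene SNPs.  The HWE test is a
permutation test: statistic |observed heterozygote count - 2 n p (1-p)|
with p the sample allele frequency, null built by re-pairing the 2N
observed alleles into N random genotypes, p-value (1 + exceedances)/
(n_perm + 1).  This re-pairing null is exactly the Levene–Haldane
conditional distribution, and the test is validated against an exact
enumeration oracle.  The FDR adjustment (Benjamini–Hochberg, via
statsmodels) is applied across the SNPs surviving the MAF filter, per
population, matching the sequential QC flow; a SNP is removed when the
adjusted p < 0.001.

Probe selection builds two lists: (A) the intersection across populations
of each population's `top_k` most variable probes ("variability" = sample
variance by default, IQR available), and (B) for every population pair,
probes ranked by variance and the top `rank_diff_frac` (default 1%) by
absolute rank difference, unioned over pairs, with boundary ties all
included (deterministic and order-independent).  The final set is (A | B)
restricted to allowed source databases (default RefSeq) and autosomes.

## Ancestry tests (`geqtl.ancestry`)

**Freeman–Halton 2 x K.**  Allele counts (two per called genotype; missing
calls excluded) per population.  The two-sided exact p sums conditional
multivariate-hypergeometric probabilities (margins fixed) of every table
with probability <= the observed, enumerated by walking the K-1 free
first-row cells with progressive outer products.  All arithmetic is in log
space (the published examples reach p ~ 1e-23).  Ties use a log-space
tolerance of 1e-9: mathematically tied tables computed through different
`gammaln` orderings can differ by ~1e-12 in relative probability, so a
tighter tolerance would drop true ties.  Above a table budget (default
5e6) the test falls back to Monte Carlo sampling from the conditional null
with the add-one estimator (1 + hits)/(reps + 1).  The enumeration is
validated against hand hypergeometric sums and scipy's 2 x 2 test; the two
modes are cross-validated against each other.

**Rank-score multivariate test (MNM).**  Probes are mid-ranked across all n
samples; with group rank means and pooled rank covariance Vhat (denominator
n - 1), W = sum_g n_g (Rbar_g - Rbar)' Vhat^{-1} (Rbar_g - Rbar).  With
denominator n - 1 the univariate no-ties case reduces *exactly* to the
Kruskal–Wallis H (var(1..n, ddof=1) = n(n+1)/12), which anchors the
implementation.  The asymptotic reference is chi-square with t(K-1) df; a
label-permutation mode is the assumption-free fallback.  Singular rank
covariance (collinear probes) falls back to the pseudo-inverse with a
warning.  The statistic is invariant under strictly monotone per-probe
transforms, as a rank test must be.

**Pharmacogenetic intersection** is an inner join on rsID between the
ancestry-informative set and a SNP list with ADR/FX/both categories; pharma
SNPs absent from the genotyping panel are reported in a "not interrogated"
sidecar, and duplicate rsIDs are deduplicated with a warning.

## Ancestry-predictive panels (`geqtl.classify`)

Flexible discriminant analysis with a linear basis is exactly linear
discriminant analysis, so the base learner is LDA on additive genotype
codes (sklearn, SVD solver; degenerate within-class scatter triggers a
1e-8-scale ridge jitter).  Forward selection adds, at each step, the
candidate with the maximum training-accuracy increment; ties are broken by
the minimum within-/between-population sum-of-squares ratio of the genotype
codes — the direction that favors the more separable marker, which is the
tie-break's purpose — and residual ties lexicographically by SNP id.
Selection stops at accuracy 1.0 or an increment < 0.001.  The outer loop is
a stratified, seeded 10-fold cross-validation; each fold reruns the whole
selection on its training portion and scores the held-out fold, and the
fold-model with the highest testing accuracy is returned (ties: smaller
panel, then lower fold index).  Candidate sets over per-population eQTL
lists follow the three standard constructions: union, intersection, and
population-specific markers.

## Synthetic data (`geqtl.simulate`)

The generator emulates a multi-population genotype + expression study:
ancestral frequencies Uniform(0.1, 0.9); population frequencies
Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) with F = 0.01 for neutral SNPs
and 0.2 for ancestry-informative ones (an `aim_delta` option plants a fixed
frequency split instead, for calibrated classifier benchmarks); genotypes
Binomial(2, p_pop), i.e. Hardy–Weinberg within populations; optional
uniform missingness; optional AR(1) correlation of latent gametes within a
gene (`ld_rho`), because inter-marker correlation is the premise of
gene-based PLS.  Expression is mu + sum_j beta_j g_j + Gaussian noise
(sigma = 1 by default; a t(5) option exists for rank-test robustness
checks), with non-target probes pure noise.  Gene coordinates are laid out
deterministically so generated matrices and the gene map are always
consistent.

What the simulator does **not** emulate: realistic LD maps, allele-frequency
spectra, expression normalization artifacts, batch effects, relatedness, or
admixture.  Passing the simulation suites therefore shows the procedures
are correctly implemented and calibrated under their own assumptions — not
that real-data genome-scale results would be reproduced.

The `tiny` fixture profile (45 samples in two populations of 23 + 22,
43 S-genes x 28 SNPs, 7 T-genes x 4 probes, two planted cis pairs and one
trans pair) mirrors the worked-example scale of the original macro's demo
data while remaining runnable end-to-end in seconds-to-minutes; the
`paper_like` profile is the four-population variant (60/60/45/45 samples).

## Problem sizes used in the test suites

Simulation suites run at n = 90 samples with 3-SNP / 3-probe blocks: 500
null pairs for the overfitting guard, 200 pairs for planted-factor
recovery, 20 planted + 180 null pairs for the scan benchmark, 500 and 400
replicates for the HWE and MNM type-I checks, 200 SNPs for FDR calibration,
and 50 replicates for the classifier power check.  These sizes make the
Monte Carlo margins quoted in the tests meaningful while keeping the suite
fast on a single CPU.

## Known limitations

- Sparse/penalized/kernel PLS variants and SIMPLS are out of scope.
- The van der Voet Hotelling approximation is not implemented.
- The exact form of the published rank-score test may differ (e.g. spatial
  ranks); the marginal mid-rank construction here is validated on its own
  terms with the Kruskal–Wallis anchor and a permutation fallback.
- SNP-to-gene assignment uses strict [start, end] overlap (1-based
  inclusive); annotation pipelines that add flanking windows can emulate
  them via the `flank` parameter.
- No LD pruning, conditional eQTL analysis, cross-population meta-analysis,
  genotype imputation, or expression normalization.
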