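# Methods

This note documents the statistical machinery, the choices made where
the design was genuinely open, and what the synthetic test surface does
and does not establish about real survey data.

## Design-based logistic regression

Point estimates maximize the probability-weighted log-likelihood
(equivalently, solve the weighted score equations) by iteratively
reweighted least squares with step-halving, a relative score tolerance
of 1e-8 (score norm measured against √Σw) and a 50-iteration cap.
Fits that hit the cap, or whose linear predictor saturates (|η| ≥ 30,
the separation heuristic), are flagged and excluded from downstream
p-value sets rather than repaired; no penalized or Firth fallback is
attempted.

Variance is the Taylor-linearization sandwich under the standard
with-replacement approximation for the first sampling stage: per-row
score contributions `u_i = w_i (y_i − μ_i) x_i` are totalled per PSU,
centered within stratum, and accumulated as
`Σ_h n_h/(n_h−1) Σ_c (z_hc − z̄_h)(z_hc − z̄_h)'`, pre- and
post-multiplied by the inverse information.  A stratum containing a
single PSU contributes its deviation from the grand mean of all PSU
totals (the "centered at grand mean" convention); no finite-population
corrections or replicate-weight methods are implemented.  Wald tests
and confidence intervals use a *t* reference with design degrees of
freedom `#PSUs − #strata`.

Two consequences worth knowing:

* Multiplying all weights by a constant changes nothing (scale
  invariance), so weights need not be normalized.
* With few PSUs the Wald *t* test is mildly anticonservative: under a
  28-PSU, 14-stratum design the empirical size at nominal 0.05 is ≈0.07
  and 95 % CI coverage ≈93 %.  This is the familiar small-PSU-count
  behaviour of linearization estimators, not an implementation defect;
  the calibration checks in the test suite therefore use designs with
  hundreds of PSUs, where size lands in [0.04, 0.06] and coverage in
  [0.93, 0.97].  Analysts of designs with very few PSUs should expect
  the same mild anticonservativeness as in mainstream survey software.

## Variable coding

Cases are defined by fasting blood glucose ≥ 126 mg/dL (boundary
inclusive); missing FBG excludes the participant from every model.
SNPs enter as numeric risk-allele dosages 0/1/2 — never factor-coded —
with the risk allele taken from a literature map, counted regardless of
VCF REF/ALT orientation.  Exposures are log₁₀-transformed (they are
long-tailed concentrations) and standardized to SD units; the moments
are computed unweighted on the full analysis sample so that per-pair
subsamples share a common scale, and are recorded in the `ExposurePanel`
so the transformation is auditable.  A survey-weighted-moments flag and
a raw-scale (no log) mode exist for sensitivity analyses.

Genetic QC reports per-ancestry allele frequencies and a 1-df Pearson
chi-square Hardy–Weinberg test without continuity correction; a
conditional exact test (log-space closed form of the heterozygote-count
distribution) is available via `method="exact"` for low minor-allele
counts.  Monomorphic samples return p = 1 by convention, flagged in the
log.

## The screen

Every (SNP, exposure) pair is fitted on its own complete-case
subsample — no common-sample restriction — mirroring assay panels that
cover different participants; subsample case/control counts are
reported per row so the imbalance is visible.  The default adjustment
set is age, sex, race indicators and BMI.  Race-stratified screens drop
the stratifying variable from the adjustment set and refuse to fit
strata with fewer than 20 cases (reported as underpowered instead); the
threshold is a package choice, configurable.  Conditional-OR exposure
levels are fixed at ±1 SD of the standardized scale.

## Effective number of tests

The eigenvalue estimator is `M_eff = 1 + (M−1)(1 − Var(λ)/M)` with
Var over the M eigenvalues using denominator M−1.  Because the
eigenvalues of a correlation matrix satisfy Σλ = M and Σλ² = ‖C‖²_F,
the variance has the closed form `(‖C‖²_F − M)/(M−1)`, which the
implementation uses: the identity and rank-1 limits (M_eff = M and 1)
are then exact in floating point.  The same identity shows the
estimator depends on correlations only through their squares, so the
"absolute correlations" variant (`use_abs=True`, kept for interface
completeness) provably returns the same value.

SNP correlations feeding M_eff are computed within ancestry strata and
pooled as the sample-size-weighted average of per-stratum matrices
(with an eigenvalue-clipping nearest-PSD repair should pooling break
positive semi-definiteness); exposure correlations are computed on the
analysis (log-standardized) scale, pairwise-complete.  The pooling rule
is a declared package choice.  Genetic and exposure counts multiply to
the total, which divides the nominal α; per-row Bonferroni-adjusted
p-values are `min(1, p·total)`.

## Parametric-bootstrap FDR

For each pair the null model (interaction dropped, both main effects
and all covariates retained) is fitted on the pair's subsample.  The
default replicate mechanism, mode `"parametric"`, draws Bernoulli
outcomes at each row's fitted null probability and refits the
interaction model, keeping the interaction p-value — the standard
parametric bootstrap for a binary outcome.  Mode `"literal"` instead
resamples the fitted probabilities themselves with replacement and
refits on those continuous dependent values via quasi-binomial IRLS;
it is retained for comparison because the resampling of *fitted* values
is one published description of the procedure, but regenerating
outcomes from the null is the well-defined default.  Refits reuse the
observed design (weights, strata, PSUs, covariates) unchanged — only
the outcome varies — so the null preserves the main-effect structure.

Failed or non-converged replicates are dropped and logged; a pair
losing >10 % of replicates is flagged.  Per-pair random substreams are
derived from the master seed and a stable hash of the pair label, so
results are reproducible regardless of execution order or parallelism.

`FDR(t) = (#{P_null < t}/B) / #{P_real < t}`; values above 1 are
reported as-is with a cap flag (they mean "everything at this threshold
is consistent with the null"), zero observed positives give NaN.  The
estimator is also evaluated at each observed p-value (threshold equal
to that p, inclusive).  Benjamini–Hochberg is deliberately not the
default — the bootstrap ratio is the contract — though nothing prevents
applying it to the same `P_real`.

## Synthetic cohorts

The generator emulates a pooled two-cycle national examination survey:

* **Design**: 14 strata × 2 PSUs by default, lognormal(σ = 0.5) weights
  drawn independently of the outcome (non-informative), with an optional
  stratum-coupled weight mode to exercise weighted-vs-unweighted
  divergence.
* **Ancestry**: five self-reported groups with oversampled minorities
  (25/5/42/22/6 %).
* **Genotypes**: 18 loci, Binomial(2, RAF) within ancestry group —
  Hardy–Weinberg by construction, no linkage disequilibrium.  One locus
  is nearly fixed (97 %) in one group to exercise the low-MAF edge.
* **Exposures**: five biomarkers, multivariate normal on the log₁₀ scale
  with a fixed correlation matrix whose salient features are a
  near-duplicate pair at ρ = 0.96 and off-diagonals spanning −0.2 to
  0.34, then exponentiated to concentrations.
* **Outcome**: logistic in dosages, standardized log-exposures,
  age/sex/BMI, and any configured interactions; the intercept is found
  by bisection so the expected case fraction hits the 9.5 % target
  (calibration error < 1 % at n = 100,000).  With all interaction
  coefficients zero the no-interaction null holds by construction.
* **Missingness**: MCAR per column (assays 25–60 %, genotypes 12 % in
  the study-like preset), which is what makes each pair's complete-case
  subsample a different size.

Default effect sizes in the study-like preset: near-null genetics
(per-allele OR 1.05–1.15) and per-SD exposure ORs from 0.6 (protective
carotenes) to 1.5–1.7 (tocopherol, organochlorine pollutants).

What passing tests on this surface do **not** show about real data:
exposures here are exactly log-normal and exactly MCAR, genotypes carry
no LD (so the genetic M_eff is essentially the full count, whereas real
genotype panels give less), weights are non-informative by default, and
there is no measurement error, batch structure or confounding beyond
the modelled covariates.  The synthetic results validate the machinery,
not the epidemiology.

## Power simulation

Power for the interaction Wald test is estimated by direct Monte Carlo:
a source population follows the logistic model with a bisection-
calibrated intercept at 9.5 % prevalence, case and control quotas are
filled by rejection sampling (retrospective design), and each replicate
is fitted by ordinary logistic ML with model-based covariance and a
normal reference — simple random sampling is assumed, matching the
conventions of standard power tools for case-control G×E design.
Estimates carry exact Clopper–Pearson binomial intervals.  Gene–
environment correlation scenarios are out of scope (independence is
assumed).

## Problem sizes in the shipped checks

The test suite and acceptance script run the full 18×5 screen at
n = 5,000 with B = 100 bootstrap replicates (9,000 refits), recovery
and coverage at n = 10,000 over 200 replicates, type-I calibration over
1,000 fits at n = 2,000, and power at 500 replicates — sizes chosen to
match the emulated study's scale while keeping a complete run in the
order of a minute or two on one CPU.
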