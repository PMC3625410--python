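# gxescreen

Systematic screening for gene–environment (G×E) interactions on a binary
disease outcome in **complex-survey data** — stratified, clustered,
probability-weighted samples of the kind produced by national health
examination surveys.  The package is aimed at epidemiologists and
biostatisticians who have (a) a panel of risk-allele-coded SNP dosages
selected from prior genome-wide association evidence, (b) a panel of
continuous exposure biomarkers selected from environment-wide
association evidence, and (c) a survey design (stratum, PSU, weight) that
must be respected for valid inference.

## The model

For each SNP–exposure pair the screen fits a survey-weighted logistic
regression on that pair's own complete-case subsample:

```
logit P(D = 1) = α + β_g·g + β_e·e + β_gxe·(g·e) + γ'·covariates
```

where `g ∈ {0,1,2}` is the risk-allele dosage, `e` is the exposure
biomarker log₁₀-transformed and standardized to SD units, and the
adjustment covariates default to age, sex, race and BMI.  Point
estimates solve the probability-weighted score equations; variance is
the Taylor-linearization sandwich built from between-PSU score totals
within strata, and Wald tests use a *t* reference with design degrees of
freedom (#PSUs − #strata).  Conditional odds ratios re-express each fit
as the per-allele OR at exposure levels −1/0/+1 SD, `exp(β_g + c·β_gxe)`,
and the per-SD exposure OR at dosages 0/1/2, `exp(β_e + g·β_gxe)`, with
delta-method confidence intervals.

Multiplicity is handled two ways:

* **Effective number of tests** (eigenvalue method): for M correlated
  factors with correlation matrix C,
  `M_eff = 1 + (M−1)·(1 − Var(λ)/M)`; the genetic and exposure counts
  multiply to the total effective tests, which divides the nominal α.
* **Parametric-bootstrap FDR**: each pair's no-interaction model
  (β_gxe = 0, main effects and covariates retained) generates B replicate
  outcomes; refitting the interaction model on each yields a null
  p-value set `P_null`, and
  `FDR(t) = (#{P_null < t}/B) / #{P_real < t}`.

A synthetic-cohort generator with fully known truth (18 SNPs with
ancestry-specific allele frequencies under Hardy–Weinberg proportions,
5 correlated log-normal biomarkers including a near-duplicate pair at
ρ = 0.96, survey structure, ~9.5 % cases, per-assay missingness) provides
the test surface for every stage, and a Monte-Carlo power module covers
design of interaction studies.

## Worked example

```python
import numpy as np
from gxescreen import *

# a survey cohort with one true interaction (OR = 2) injected
spec = study_spec(n_participants=6000, seed=7,
                  beta_gxe={("snp01", "trans_b_carotene"): np.log(2.0)})
syn = generate_cohort(spec)
panel = ExposurePanel(columns=spec.exposure_ids)
prepared = transform_exposures(syn.cohort, panel)

table = interaction_screen(prepared, syn.design, spec.snp_ids, spec.exposure_ids)
print(table.head(3)[["snp", "exposure", "or_gxe", "p", "n_cases", "n_controls"]])

pairs = list(table.loc[table["converged"], ["snp", "exposure"]].itertuples(index=False))
null = bootstrap_null(prepared, syn.design, pairs, B=100, seed=8)
fdr = estimate_fdr(p_real(table), null["p"].to_numpy(), B=100, thresholds=[0.05])
print(f"FDR(0.05) = {fdr.at_threshold[0.05]:.3f}")
```

Output:

```
  snp         exposure   or_gxe            p  n_cases  n_controls
snp01 trans_b_carotene 2.328558 6.073799e-08      384        3381
snp01   cis_b_carotene 2.000947 2.604773e-07      362        3328
snp06   cis_b_carotene 0.693097 8.754269e-03      360        3388
FDR(0.05) = 0.820
```

The injected pair tops the 90-row screen (interaction OR 2.33,
p = 6×10⁻⁸ against a Bonferroni-style adjusted α of ~6×10⁻⁴), and its
near-duplicate biomarker (ρ = 0.96 with the true one) ranks second — a
deliberate feature of correlated exposure panels.  The overall FDR(0.05)
is high because all other 88 pairs are null by construction, so most
p < 0.05 results are expected false positives.  The conditional ORs of
the top fit show the interaction's shape: per-allele OR 0.48 (0.37–0.63)
at exposure 1 SD below the mean versus 2.60 (2.00–3.37) at 1 SD above.

The same workflow runs from the shell:

```bash
gxescreen simulate --n 6000 --seed 7 --gxe snp01:trans_b_carotene:2.0 --out cohort.tsv
gxescreen report config.yaml     # QC -> scans -> screen -> Meff -> bootstrap FDR
gxescreen power grid.yaml --out power.tsv
```

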