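# Methods

This note documents the generative model, the estimators, the numerical
choices and the known limitations of `adipomr`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Generative model (`adipomr.simulate`)

The simulator emulates the statistical structure of a biobank-scale MR
analysis of adiposity and mental health:

- **Genotypes.** M independent biallelic SNPs, dosages gᵢⱼ ~ Binomial(2, pⱼ)
  under Hardy–Weinberg, minor-allele frequencies drawn uniformly from
  `maf_range` (default (0.05, 0.5]). SNPs are simulated without linkage
  disequilibrium: the instruments being emulated are genome-wide-significant
  independent loci, so LD would add nothing the estimators consume.
- **Exposure.** X = Σⱼ γⱼgᵢⱼ + a·Uᵢ + εᵢ on the standardized scale; γⱼ has a
  random positive magnitude and is rescaled so Var(Σγg)/Var(X) equals
  `exposure_h2`. Default h² = 0.016, the variance a 72-SNP BMI score explains
  in a large European-ancestry biobank; the favourable/unfavourable adiposity
  presets use h² = 0.002 (36 SNPs) and 0.006 (38 SNPs). U is standard normal
  and feeds both exposure and outcome (slopes `confounder_effect_*`, default
  0.3 each — moderate confounding, enough to visibly bias the observational
  contrast without dominating it). A raw BMI-like scale (mean 27.4, SD 4.6
  kg/m²) is carried alongside for stratified analyses.
- **Outcome.** Latent η = f(X) + b·U + Σⱼ αⱼgᵢⱼ + ε with f linear, quadratic
  or hinge ("threshold"). Continuous outcomes return η with unit residual
  noise. Binary outcomes are Bernoulli(expit(c₀ + η)) with c₀ solved by
  bisection so the mean prevalence matches `binary_prevalence` (tolerance
  1e-4 on the mean; default prevalence 0.018, a current-depression-like
  rate). Because the outcome is rare, the marginal per-allele association is
  ≈ θγⱼ (log-link collapsibility), which the recovery tests rely on.
- **Pleiotropy.** αⱼ = 0 (`none`); N(0, sd) (`balanced`); N(mean, sd)
  (`directional`); or ρ·γⱼ + noise (`inside_violating`) — the standard
  construction for breaking the InSIDE assumption and demonstrating Egger
  bias.
- **Covariates.** Age, sex, assessment centre, deprivation index and smoking
  are simulated independent of genotype, so adjusted and unadjusted estimates
  can be contrasted and adjustment sets exercised.
- **Determinism.** One `numpy` Generator seeded from the config drives every
  draw; identical configs give bit-identical cohorts.

What the simulator does **not** emulate: relatedness/population structure,
item-level questionnaire coding, LD, genotyping error, or selection into the
study. Passing recovery tests therefore demonstrate estimator correctness
under the model's assumptions, not robustness to those real-data features.

### Summary statistics

`cohort_to_summary_stats` splits a cohort into disjoint halves (seeded
permutation), estimates per-SNP exposure associations in subset 1 by simple
linear regression and outcome associations in subset 2 (linear, or logistic
for binary outcomes), giving genuinely two-sample statistics.
`simulate_summary_stats` generates instrument sets directly at the summary
level — true γⱼ plus sampling noise implied by the two GWAS sizes — which is
how the Egger/median calibration experiments reach thousands of replicates
cheaply. Its default discovery size (339k, with a 5M option used in the
calibration experiments) keeps measurement error in γ̂ negligible, matching
the NOME regime MR-Egger assumes.

Single-predictor regressions are computed by closed-form OLS and a
vectorised 2-parameter Newton–Raphson logistic kernel (`_regress.py`); the
acceptance experiments run tens of thousands of such fits and per-fit model
machinery would dominate the runtime. The kernels are cross-checked against
statsmodels in the unit tests; all multi-covariate models (observational
regressions, 2SLS stages) use statsmodels directly.

## Phenotypes

The inverse-normal transform is the Blom rankit,
z = Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties (deterministic).
Observational models are maximum-likelihood logistic (tolerance 1e-8,
iteration cap 100; non-convergence and perfect separation raise, never return
silently) or OLS, reporting effects per 1-SD exposure; sex-stratified fits
drop sex from the adjustment set.

## Instruments

Risk scores use **external** discovery weights, not internally re-estimated
ones, avoiding winner's-curse bias; in simulation the "discovery study" is
the generating truth perturbed by discovery-scale sampling noise
(`discovery_weights`). Dosages flip (d → 2−d) when a weight's effect allele
matches the genotype's other allele, with strand resolved by base complement;
unresolvable variants are excluded with a logged reason.

Harmonization aligns outcome to exposure alleles (sign-flipping swapped
variants, complementing strands), then orients every variant to the
exposure-raising allele. Palindromic (A/T, C/G) variants with exposure-side
EAF in [0.42, 0.58] are excluded as strand-ambiguous; outside that window the
allele frequencies settle the strand. The output is a normal form:
re-harmonizing it is a no-op, and Wald ratios are invariant to simultaneous
allele flips.

Instrument strength: R² of exposure on the score and F = R²(n−2)/(1−R²);
F < 10 sets the weak-instrument flag.

## One-sample MR

2SLS: stage 1 regresses the (inverse-normalized) exposure on the score plus
covariates; stage 2 regresses the outcome on the fitted values plus the same
covariates. Covariates enter both stages — the standard 2SLS contract. For
linear outcomes the SE is rebuilt from proper 2SLS residuals (y − Xβ̂ with
the observed exposure). For binary outcomes the stage-2 logistic model SE is
reported as-is; this is exactly the two-stage procedure described for
biobank practice and its known caveats (non-collapsibility, uncorrected
second-stage SE) motivate the optional individual-resampling bootstrap
(`se_method="bootstrap"`, default 1000 seeded draws). With a single
instrument and linear stages the estimator reduces algebraically to
cov(G,Y)/cov(G,X), which the tests verify to 1e-10.

## Two-sample MR

- **Wald ratio.** θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order delta SE se(Γ̂ⱼ)/|γ̂ⱼ|
  (consistent with NOME); a second-order option adds the exposure-side term.
- **IVW.** Inverse-variance-weighted mean with *multiplicative*
  random-effects: SE × max(1, √(Q/(k−1))). The multiplicative model is the
  MR-standard reading of "random-effects IVW"; the floor at 1 means
  heterogeneity can widen but never narrow the interval. P-values are
  normal-theory.
- **MR-Egger.** WLS of Γ̂ on γ̂ with intercept, weights 1/se(Γ̂)²; the
  intercept (its SE, p) is the directional-pleiotropy test. Both SEs carry
  the same multiplicative scaling with k−2 df. A t-option (k−2 df) exists;
  the default is normal, consistent with the other estimators. A collinear
  design (all γ̂ equal) raises rather than silently splitting slope and
  intercept.
- **Weighted median.** Sort θ̂ⱼ; normalized weights pⱼ; cumulative midpoints
  sⱼ = Σ_{i<j}pᵢ + pⱼ/2; linear interpolation of θ̂ against s at s = 0.5.
  The estimator is consistent while valid instruments hold >50% of weight;
  note the finite-sample estimate equals a dominant variant's ratio only in
  the limit of its weight share → 1 (interpolation smooths the crossing).
  SE by parametric bootstrap: resample γ̂ⱼ, Γ̂ⱼ from N(observed, SE), default
  1000 seeded draws.
- **Penalized weighted median.** qⱼ = wⱼ(θ̂ⱼ − θ̂_WM)²; penalty
  w′ⱼ = wⱼ·min(1, 20·pⱼ) with pⱼ the upper-χ²₁ tail of qⱼ (penalty constant
  20 from the original construction, exposed as a parameter); the median is
  re-run with w′, inside each bootstrap draw as well.

## Non-linear MR

The exposure is residualized on the score (linear IV-exposure effect
assumed) and re-centred at the exposure mean so stratum boundaries live on
the raw (kg/m²-like) scale; the sample is cut into equal-count strata of
this IV-free exposure (deciles a priori; ties broken by stable rank). The
IV-free residual is used for stratification because stratifying on the raw
exposure — a collider of instrument and confounder — would re-introduce
confounding within strata.

Within each stratum the LACE is the ratio of the outcome-on-score to the
exposure-on-score slope (logistic numerator for binary outcomes → log-odds
per raw exposure unit), with first-order delta SE on the numerator.
Denominators are re-estimated per stratum rather than borrowed from the full
sample. Strata with fewer than 30 individuals, fewer than 10 cases, or a
denominator within 2 SE of zero are flagged and their LACE withheld; flagged
strata stop the curve (the chain rule below needs every segment) with an
explicit error listing them.

The piecewise-linear curve sets value(b₀) = 0 at the lowest boundary and
value(bₖ) = value(bₖ₋₁) + LACEₖ·(bₖ − bₖ₋₁): continuous by construction, an
identity the tests assert at every knot. Pointwise 95% bands come from
resampling individuals *within* strata (sizes preserved; default 500 seeded
draws; resamples run through the same vectorised kernels). Non-linearity
tests: Cochran's Q of the LACEs against their IVW mean (χ², S−1 df) and the
quadratic test — inverse-variance-weighted regression of LACEⱼ on the
stratum mean exposure (slope, SE, normal p). Covariate adjustment of the
within-stratum regressions is deliberately not applied (exposed nowhere);
the stratification argument above is the design's control for confounding,
and the simulated covariates are genotype-independent.

Fractional-polynomial curve fitting is intentionally out of scope; the
piecewise-linear function is the only implemented method. Post-hoc
refinements of stratified MR (e.g. doubly-ranked stratification) are not
implemented.

## Pipeline

`run(config)` executes instrument-set × outcome × stratum × method cells,
isolating failures per cell as `withheld`/`error` rows with reasons (e.g.
sex-stratified rare-binary non-linear cells are typically withheld for
insufficient per-decile cases — the same power limit the underlying study
reports for its underweight stratum). Two-sample methods run on the
whole-sample summary statistics only; sex-stratified rows for them are
withheld with that reason, since stratified GWAS are not part of the design.
All randomness descends from the config seed through a `SeedSequence` spawn
tree, outputs are written with fixed float formatting and a manifest records
the config hash, seed and package version: reruns are byte-identical.
Nominal p-values are reported throughout (matching the analysis being
reproduced); an optional Bonferroni column can be added, clearly labelled.
One-CPU execution is the contract; cells are independent but no concurrency
is used.

## Calibration experiments (`adipomr.calibration`)

Problem sizes are the package's desk-scale choices: 200 replicates of
two-sample recovery at 20 000 per sample; 2000 summary-level instrument sets
for Egger calibration; 500 replicates for median robustness; 1000 for
non-linearity type-I error; 200 for quadratic power.

- The **median robustness** experiment gives 30 of 72 instruments strong
  directional pleiotropy and conditions on those instruments holding <50% of
  the inverse-variance weight (the estimator's validity premise), with
  precise summary associations on both sides so the breakdown-point property
  — not ratio noise — is what's measured.
- The **penalization** experiment contaminates a single *strong* instrument
  (an FTO-like variant carrying ~20% of the weight): a random low-weight
  outlier barely moves the plain weighted median, so the contrast is run in
  the configuration the Q-penalty exists for.
- The **quadratic power** coefficient (0.1 per squared SD of exposure) was
  sized a priori from the delta-method SE of decile LACEs at n = 20 000 so
  the test sits in its high-power regime.

## Known limitations

- Stage-2 logistic SEs in one-sample MR are uncorrected model SEs (bootstrap
  available); log-odds 2SLS estimates are non-collapsible marginal effects.
- Rare binary outcomes at small case counts make per-SNP logistic estimates
  and their estimated precisions correlate, which can push summary-MR pooling
  slightly away from the null even as weak-instrument dilution pulls it
  toward the null; the acceptance script reports both the split-sample design
  and the external-discovery design so the two regimes are visible.
- The weighted-median bootstrap is parametric (normal resampling of the
  summary statistics), not a resampling of individuals.
- No LD, relatedness, population structure or selection; instruments are
  assumed pre-pruned; VCF ingestion is limited to what the simulator and TSV
  interfaces cover.
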