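# Methods

## Scope and model

`ocumix` implements a population-ophthalmology analysis chain for the
question of how education shapes ocular biometry:

1. **Distribution modelling.** Spherical equivalent (SE, diopters) and
   axial length (AL, mm) in adult populations are not well described by a
   single Gaussian; a two-component ("bi-Gaussian") mixture captures an
   emmetropized majority plus a myopic, longer-eyed subgroup.  We fit
   univariate K-component Gaussian mixtures by EM and compare K via
   AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln n with p = 3K − 1 (K − 1 free
   weights, K means, K SDs).  The minimal criterion wins; ties go to the
   smaller K.
2. **Genetic risk scores.** S_i = Σ_j d_ij β_j over effect-allele dosages
   d ∈ [0, 2] and published per-allele weights; for signed panels
   (education) the positive- and negative-weight sub-sums are reported
   separately, and scores are standardized (n − 1 denominator) for
   per-SD reporting.
3. **Association models.** Linear models of each biometric outcome on
   education years adjusted for age, sex (female = 0, male = 1) and the
   myopia GRS.  Inference is sandwich-robust: HC1 on person-mean rows, or
   cluster-robust over persons when per-eye rows are analysed — the
   working-independence GEE surface.  CIs are estimate ± 1.96·SE.
4. **Mediation.** Difference method: proportion mediated
   PM = (β_marginal − β_conditional)/β_marginal, where the conditional
   model adds the mediator (AL).  Percentile bootstrap over persons
   (default B = 1000) supplies CIs.  Point estimates coincide with
   joint-estimating-equation mediation estimators in the linear,
   no-interaction case; the bootstrap replaces their analytic inference
   for transparency.  PM is undefined when |β_marginal| < 1e−12.
5. **Mendelian randomization.** One-sample summary-statistic MR: per
   variant, β_x/se_x and β_y/se_y from linear models of exposure and
   outcome on dosage + (age, sex), computed by residualizing on the
   shared covariate design (Frisch–Waugh–Lovell).  Estimators: IVW
   (fixed-effect; weights 1/se_y²), simple and weighted median (weights
   β_x²/se_y², first-order; parametric-bootstrap SEs, B = 2000), and
   MR-Egger (intercept = average directional pleiotropy; SEs inflated by
   max(1, √(RSS_w/(J−2)))).  Variants are oriented so β_x ≥ 0.  The
   exposure is z-scored by default so estimates read "per SD of
   exposure".  Both betas are estimated in the same cohort (one-sample
   design) — weak-instrument bias therefore points toward the
   observational association, a documented caveat.

## Synthetic cohorts

Individual-level data of the source population study are not deposited,
so a generator (`ocumix.synthetic`) produces cohorts with the structure
the analyses assume.  Calibration anchors are the published descriptive
statistics (AL 23.74 ± 1.22 mm, SE −0.41 ± 2.51 D, education
13.05 ± 2.09 y, ACD 3.25 ± 0.35 mm, CC 7.84 ± 0.28 mm, LT 4.35 ± 0.37 mm,
WTW 12.21 ± 0.43 mm) and the published effect estimates.  Scenario
highlights:

* **regression** — β(edu→AL) = 0.06 mm/y, β(AL→SE) = −1.0 D/mm, direct
  β(edu→SE) = −0.04 D/y, so the total adjusted education effect on SE is
  −0.10 D/y; β(edu→ACD) = 0.01 mm/y; CC/LT/WTW null.  Residual SDs are
  solved in closed form so the marginal SDs match the anchors.
* **mediation** — β(AL→SE) = −2.1 D/mm and direct −0.054 D/y give a
  marginal effect of −0.18 D/y and proportion mediated 0.70.
* **mr** — 50,000 persons; 70 education SNPs jointly explaining 5% of
  education variance (per-SNP F ≈ 35); causal effects −0.35 D and
  +0.63 mm per SD of education; 53 myopia and 21 axial-length SNPs with
  direct effects (each score R² ≈ 0.05) instrument the reverse analyses,
  which are null by construction.  Pleiotropy is off by default (Egger
  intercept ≈ 0); a knob adds directional direct-on-SE effects to a
  fraction of education SNPs for robustness studies.
* **bimodal** — AL ~ 0.72·N(23.45, 0.85²) + 0.28·N(25.10, 1.20²), SE tied
  to AL at −2.0 D/mm.  Persons with < 11 education years are assigned to
  the emmetropic component; the long-education assignment probability is
  solved so the overall weights hold.  A softer preferential link (e.g.
  85%) leaves enough contamination in the ~16% short-education stratum
  that BIC detects the second component again — full assignment is what
  reproduces the qualitative finding that the short-education stratum is
  Gaussian, and that is the stated purpose of the scenario.

Other generator choices: age ~ Uniform(40, 80) (the source design
stratified by age decade); education is continuous and clipped to
[0, 20] after noise; sex shifts AL by ±0.29 mm (male +), matching the
~0.58 mm published sex gap; the myopia GRS shifts SE by −0.30 D per SD
in the regression/mediation scenarios (a choice — the source reports no
per-SD effect); dosages are Binomial(2, p) with p ~ Uniform(0.1, 0.9)
and no LD; per-eye values add independent noise (AL 0.25, SE 0.45,
ACD 0.10, CC 0.08, LT 0.10, WTW 0.15 — invented magnitudes that only
exercise eye averaging).  All draws flow from one `numpy` Generator, so
(config, seed) reproduces every table bit-for-bit.

What the generator does **not** emulate: linkage disequilibrium,
Hardy–Weinberg violations, imputation uncertainty, measurement error
correlated between eyes, confounding between education and biometry, and
age effects on biometry.  Passing tests therefore demonstrate that the
estimators recover known structure under clean conditions, not that the
published estimates are correct in real data.

## Numerical choices

* EM: responsibilities in log space (log-sum-exp); convergence when the
  relative log-likelihood change < 1e−8 or 500 iterations (flagged, not
  fatal); SD floor 1e−3 × sample SD; initialization at the
  (k − 0.5)/K sample quantiles plus random mean perturbations across
  restarts (default 4, best likelihood wins); K = 1 uses the closed-form
  MLE and needs only n ≥ 2, K ≥ 2 needs n ≥ 3K.
* Education strata are half-open [lo, hi) bands, the last closed, with
  the short band `edu < 11` ("0–10 years" for integer years); strata
  under 50 observations are skipped.
* Person-level filters: "over 70" excludes age > 70 (70 kept); the
  hyperopia sensitivity cut defaults to person-mean SE > +0.75 D — the
  source states no numeric cutoff, so it is configurable; a person
  non-phakic in either eye is excluded entirely.
* Weighted median: sort ratios, cumulative weights minus half-weights,
  linear interpolation at 0.5, clamped at the extremes.
* p-values are two-sided normal everywhere (matching the ±1.96 CIs).

## Problem sizes used in the checks

The recovery suites regenerate scenarios at the study scale (8,532
persons; 50,000 for MR) with replicate counts chosen to keep the whole
suite within a desktop run: 50 replicates for the regression
coefficients, 20 for mixture selection (2 restarts there), 5 for the MR
battery, 60 at n = 4,000 for CI coverage, and 12 at n = 20,000 for the
pleiotropy-robustness comparison.  Replicated checks pass when at least
the stated fraction of replicates hit (e.g. ≥ 90%), which makes them
robust to the expected rate of legitimate 3-SE excursions.

## Known limitations

* The bi-Gaussian component parameters are generator choices; the source
  prints none, so the bimodal scenario is qualitative.
* The mediation marginal effect (−0.18 D/y) and the adjusted association
  (−0.10 D/y) come from differently adjusted models in the source and
  are deliberately reproduced by *different* scenarios.
* MR-Egger inference uses the simple multiplicative overdispersion
  factor, not SIMEX or bootstrap; medians use first-order weights.
* No support for binary outcomes, exposure–mediator interaction, or
  multivariable MR.
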