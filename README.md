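# ocumix

Ocular biometry distribution modelling and causal epidemiology in Python:
for researchers asking how education shapes refractive error and eye
anatomy at the population level.

In adult populations, spherical equivalent (SE, diopters; negative =
myopic) and axial length (AL, mm) are not simple Gaussians: they behave
as a **bi-Gaussian** mixture — an emmetropized majority plus a myopic,
longer-eyed subgroup — and the split is partly explained by length of
education. `ocumix` packages the full analysis chain around that
observation:

* **Gaussian mixture modelling** — univariate K-component EM fits with
  AIC/BIC model selection (p = 3K − 1), overall and stratified by
  education bands;
* **genetic risk scores** — S_i = Σ_j d_ij β_j over allele dosages, with
  positive/negative sub-sums for signed panels and allele harmonization;
* **association models** — education → {SE, AL, corneal curvature,
  anterior chamber depth, lens thickness} adjusted for age, sex and the
  myopia GRS, with sandwich (HC1 or person-clustered) standard errors;
* **mediation** — difference method, PM = (β_marg − β_cond)/β_marg, with
  percentile-bootstrap CIs, quantifying how much of the education→SE
  effect runs through axial elongation;
* **Mendelian randomization** — one-sample, bidirectional
  (education ⇄ SE, education ⇄ AL), with IVW, simple median, weighted
  median and MR-Egger (intercept = pleiotropy test);
* **synthetic cohorts** — a seeded generator whose frozen scenarios are
  calibrated to published population estimates, so every stage is
  testable without access to individual-level data.

## Worked example

```python
from ocumix import scenario_default, generate_cohort, person_eye_means
from ocumix.mixture import stratified_mixture_report
from ocumix.mediation import difference_mediation

cfg = scenario_default("bimodal"); cfg.seed = 20
cohort, dosages, panels, truth = generate_cohort(cfg)
persons = person_eye_means(cohort)          # mean of both eyes per person
print(stratified_mixture_report(persons, "al", seed=0)
      [["stratum", "n", "k_aic", "k_bic", "bic_k1", "bic_k2"]].round(1))
```

```
  stratum    n  k_aic  k_bic  bic_k1  bic_k2
  overall 8532      2      2 27710.1 27183.8
 edu_0_11 1439      1      1  3741.9  3760.0
edu_11_20 7093      2      2 23469.2 23061.1
```

Axial length is bimodal overall (BIC 27183.8 for two components vs
27710.1 for one) and in the long-education stratum, but a single
Gaussian wins in the 0–10-year band — the short-education subgroup is
the physiologically emmetropized one.

```python
cfg = scenario_default("mediation"); cfg.seed = 20
persons = person_eye_means(generate_cohort(cfg)[0])
res = difference_mediation(persons, "se", "education_years", "al",
                           ["age", "sex"], B=500, seed=1)
print(res.beta_marginal, res.beta_conditional, res.proportion_mediated)
```

```
marginal -0.206  conditional -0.049  proportion mediated 0.76 (95% CI 0.70-0.81)
```

Each additional education year is associated with a −0.21 D myopic
shift; conditioning on axial length shrinks it to −0.05 D, i.e. roughly
three quarters of the effect runs through eye elongation.

A `click` CLI mirrors the library (`ocumix simulate`, `fit-mixture`,
`grs`, `assoc`, `mediate`, `mr`, `run-all`); `ocumix run-all --scenario
mr --seed 1 --out run/` writes the full report bundle (tables, manifest,
log) and `ocumix mr --summary-stats s.tsv` runs the four MR estimators
directly on a TSV of per-variant summary statistics.

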