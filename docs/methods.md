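# Methods

## Problem and metrics

Care coordination among outpatient providers is commonly proxied by
*patient-sharing*: two providers who bill services for the same patients are
likely to have a working relationship. For each calendar year, `carenet`
builds an undirected provider graph in which the edge weight `w_i` of a
provider pair counts the patients of a broad psychiatric reference cohort
who visited both providers that year. Edges with fewer than `min_w = 3`
shared patients are removed; the small absolute threshold keeps connections
to low-volume provider types (psychotherapists) while removing incidental
sharing.

For an outcome quarter, a patient's network consists of the providers
visited during the preceding two quarters (the lookback window). With
`n_p` providers and `m = n_p (n_p - 1) / 2` unordered pairs, **care
density** is

```
C_p = (sum_i w_i) / m ,
```

the average number of shared patients across all pairs of the patient's
providers — including visited pairs with no graph edge, which enter with
weight 0. `C_p` is undefined for `n_p < 2`; this state is carried as an
explicit sentinel and becomes an indicator variable in regression models,
never a numeric 0 or NaN.

**Fragmented care density (FCD)** decomposes the numerator by *connection
type* — the unordered pair of provider specialties, same-specialty pairs
included, so `k = l(l+1)/2` types for `l` specialties (15 for the default
registry GP, psychiatrist, neurologist, neurologist/psychiatrist,
psychotherapist). Each type's normalized sum `s_j / m` is categorized
against tertiles of its positive training-period distribution into
missing / weak / moderate / strong link indicators. A logistic model with a
subject random intercept regresses quarterly hospitalization on these `3k`
indicators plus control variables; the fitted coefficients are the
connection-type weights. The FCD score of a patient-quarter is the model's
linear predictor with all controls fixed at their training means, so score
differences between patients reflect network differences only. Patients
with no links score the intercept-plus-offset base risk.

Tertile coding makes the metric robust to the extreme outliers that raw
shared-patient counts exhibit (a few group practices share hundreds of
patients) and allows non-linear, non-monotone effects of link strength —
the two failure modes of the linear-in-weight care density.

## Two-stage design

The study timeline per patient is anchored at the index quarter (earliest
qualifying diagnosis in the index year): a 4-quarter preperiod supplies
fixed covariates; follow-up covers 8 quarters starting one year after the
index quarter; the first 4 follow-up quarters are the **training year** and
the last 4 the **validation year**. Tertile cutpoints and connection-type
weights are estimated on the training year and then frozen. Validation-year
networks are coded with the frozen cutpoints and collapsed to one FCD score
per patient-quarter. Model comparison on the validation year asks whether
adding either care density (2 parameters: the 0-filled value plus the
undefined indicator) or the FCD score (1 parameter) improves a
controls-only baseline, using likelihood-ratio tests, AIC and BIC.
Decile-level effects are reported as relative hospitalization risks of
score deciles against the median decile, predicted for a population-median
subject (random intercept 0) with controls at their means; the median's
relative risk is 1 by construction.

Whether a two-quarter-confirmed outpatient diagnosis counts in the first or
second quarter of its pair, and the offset between index quarter and
follow-up start, are not uniquely determined by the design; both are
configuration options (`outpatient_validated_quarter = "first"`,
`followup_start_offset = 4` by default). The first-quarter convention uses
the earliest documented evidence; the 4-quarter offset separates the
weight-estimation data cleanly from the diagnosis period.

## Random-intercept logistic model

Quarterly hospitalization `y_it` follows

```
y_it | u_i ~ Bernoulli( expit( x_it' beta + u_i ) ),   u_i ~ N(0, sigma^2),
```

and estimation maximizes the marginal likelihood with the subject effects
integrated out by adaptive Gauss–Hermite quadrature: per subject the
integrand is re-centered at its posterior mode and re-scaled by the
curvature there (mode finding is a vectorized Newton iteration; the mode
problem is concave). Default 15 nodes; one node reproduces the Laplace
approximation. On reference datasets the 15- and 25-node log-likelihoods
agree to well below 1e-6, and the fit matches `lme4::glmer(nAGQ = 15)` to
about 1e-5 in log-likelihood and coefficients.

Numerical choices:

- Optimization is L-BFGS-B on `(beta, log sigma)` initialized from the
  plain logistic MLE and `sigma^2 = 0.1`, with the score computed from
  posterior-weighted quadrature nodes (for rules under 5 nodes the score is
  finite-differenced instead, because the neglected mode-dependence terms
  are no longer negligible). The projected-gradient tolerance scales as
  `1e-6 * sqrt(n_obs)`.
- `log sigma` is bounded below at -6.9; the likelihood is flat in
  `log sigma` as `sigma -> 0`, and a boundary fit (`sigma^2 ~ 1e-6`)
  represents the no-heterogeneity solution. When the true variance is 0 the
  variance MLE is the usual boundary/positive mixture across realizations;
  positive draws are genuine maxima (confirmed against `glmer`), not
  optimizer artifacts.
- Standard errors come from the observed information (central differences
  of the score); AIC = -2 logL + 2p and BIC = -2 logL + p log(n_subjects),
  counting the variance component in p and using the number of subjects as
  the BIC sample size, the convention of common mixed-model software.
- Coefficients beyond ±15 raise a quasi-separation warning flag;
  non-convergence raises an error carrying the final gradient norm.

**Inestimable link weights.** At moderate sample sizes some of the `3k`
dummies fire in only a handful of patient-quarters, or fire only in rows
with a single outcome value; the ML estimate for such a dummy is unbounded
and a single wild coefficient would contaminate every downstream score.
Dummies with fewer than 5 firing rows, with one-sided outcomes, or with a
fitted |beta| > 10 are therefore folded into the missing reference
(weight 0), the same treatment a category never observed in training
receives. This is a desk-scale safeguard; at claims-registry sample sizes
it is inactive for all common connection types.

## Synthetic claims generator

The generator (`carenet.simulate`) emulates the structural features of
statutory-insurer claims the pipeline depends on, with defaults chosen to
mirror the documented environment of such data:

- **Provider landscape.** Five specialties with strongly asymmetric volume
  (32 GPs with heavy-tailed lognormal volume, sigma 1.2; 16 psychiatrists;
  12 neurologists; 16 neurologist/psychiatrists; 24 low-volume
  psychotherapists) spread over 8 communities; GPs form two-physician group
  practices within communities.
- **Panels and visits.** Each patient holds a persistent panel: a primary
  GP, extra GPs with probabilities (0.52, 0.28, 0.13, 0.07) for 0–3
  (a second GP is the practice partner with probability 0.85), and each
  specialist kind with probabilities 0.38/0.22/0.32/0.15 (PSY/NEU/NP/PT),
  plus a 0.12 chance of a parallel second specialist of a present kind.
  Panel members are retained quarter-to-quarter with probability 0.92 and
  visited with specialty-specific probabilities around 0.5. These settings
  reproduce: a quarterly hospitalization rate near 9% (within the 5–11%
  band typical of severe-mental-illness cohorts), roughly a third of
  patient-quarters with fewer than two providers, GP–GP connections
  carrying the largest share of total shared patients, and GP–GP / GP–PSY
  / GP–NP link prevalences near 25% / 25% / 20%.
- **Outcomes.** Hospitalizations are drawn from exactly the model the
  estimator fits: the configured link effects are applied to the same
  tertile dummies the estimator will construct (cutpoints fitted on the
  generated training year and frozen), plus control effects (age in SD
  units -0.30, depression comorbidity -0.10, substance abuse +0.45,
  specialist contacts +0.10), a subject random intercept
  (`sigma^2 = 0.4`), and an intercept centered so the population event rate
  hits the 7% target. This makes the estimand well-defined and recovery
  exact in expectation. Ground truth (including the realized cutpoints) is
  stored with every bundle.
- **Scenarios.** `null` has no link effects (type-I calibration).
  `signal` uses a weight pattern in which strong GP×(neuro)psychiatrist
  cross links protect (strong GP–PSY fixed at -0.40) while weak
  same-specialty links harm (weak GP–GP +0.50); magnitudes are balanced so
  that the mean link effect of patients *with* a network is slightly
  positive and the covariance between care density and the true linear
  predictor is near zero. Under this truth a linear function of total
  shared patients carries almost no signal while the tertile-coded score
  does — the regime the two metrics are designed to distinguish.
  `cd_confounded` has no link effects but a latent utilization trait that
  inflates both panel size (hence care density) and hospitalization risk.
- **Determinism.** Each table draws from its own stream split off the
  master seed, so bundles are byte-identical under a repeated (scenario,
  seed) and adding a table never perturbs earlier ones.

What the generator does **not** emulate: real diagnosis code strings,
geographic structure beyond exchangeable communities, provider entry/exit,
seasonal utilization, death and coverage churn (supported by the cohort
rules but not generated by default), and any correlation between control
variables and network structure beyond the specialist-contact count.
Passing tests therefore demonstrate internal statistical correctness of the
pipeline under a realistic generating law — not that FCD outperforms CD in
any particular real claims population.

## Study sizes used in the test suite

Replicate studies are sized for a single CPU: parameter recovery uses 100
replicates of 2,000 patients × 4 training quarters; type-I calibration 200
replicates of 400 patients; the two-stage FCD-vs-CD comparison 50
replicates of 3,000 patients. The acceptance script runs one full two-stage
analysis on 3,000 patients.

## Known limitations

- The FCD weights are estimated without shrinkage; rare connection types
  are folded into the reference rather than partially pooled. A penalized
  or hierarchical weight model would be a natural extension.
- Only undirected patient-sharing networks are supported (no referral
  direction), and only a single two-quarter lookback convention per run.
- When a lookback window straddles two calendar years, the sharing graph of
  the later year is used; averaging the two adjacent years is a defensible
  alternative and is deliberately not mixed into the default.
- Relative-risk-by-decile predictions condition on the median subject
  (random intercept 0) rather than averaging over the random-intercept
  distribution; marginal (population-averaged) risks would be attenuated
  toward 1.
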