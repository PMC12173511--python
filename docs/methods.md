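# Methods

`papiokit` studies a question from wild-primate behavioural ecology: do a
juvenile female's early-life relationships with her father — how much they
groom, and how long they live in the same social group — predict how long
she lives as an adult, over and above the cumulative early-life adversity
she experienced? Because the field data behind such analyses are
long-running observational studies, the package pairs every analysis stage
with a synthetic-population generator whose ground truth is known, so each
estimator can be validated by parameter recovery rather than by eyeballing.

## The dyadic sociality index (DSI)

For each juvenile female, each co-resident adult male, and each year of her
life (birthday to birthday, ages 0–3), the pair's grooming count is turned
into a daily rate over their co-resident days, log-transformed with a fixed
floor, regressed on observer effort, and the residual z-scored within the
year-of-life stratum:

```
rate   = events / co-resident days          (dyads with >= 30 days)
log_r  = log(rate + eps),  eps = 1/3650
resid  = log_r - OLS(log_r ~ effort)        (fit within stratum)
DSI    = (resid - mean) / sd                (within stratum, n-1 sd)
```

* `eps = 1/3650` (one event per ten observation-years) guarantees every
  zero-grooming dyad — co-resident or not — shares a single floor value,
  which the father-absent years require: a female whose father left before
  her birth must get the same paternal score as one whose co-resident
  father never groomed her.
* The 30-day co-residency threshold gates entry into `DSI_all` and
  `DSI_non-paternal`; father dyads are always scored (`DSI_paternal`),
  using the floor when co-residency is zero.
* Stratification is by year of life across the whole population, pooling
  groups and calendar years; a calendar-year mode would be an alternative
  reading and the stratum column is a parameter of
  `adjust_for_effort`/`zscore_within_stratum`. One consequence of
  year-of-life stratification is that the *age main effect* of any model of
  DSI across years is absorbed by the standardization: only contrasts
  within a stratum (such as father vs. non-father) survive. The package's
  headline dyadic model therefore targets the father term.
* Effort is joined to a birthday-aligned window as the day-weighted mean of
  the group-calendar-year values the window overlaps.
* Per-female summaries re-standardize the annual values across females
  within each year of life before averaging, so each juvenile year
  contributes on a common scale.

The adult social connectedness indices (`SCI_F`, `SCI_M`) apply the same
rate → effort-residual → z-score construction to an adult female's total
grooming given and received with adult females and adult males, one value
per adult year (>= 30 resident days), averaged over adult years.

## Cumulative early-life adversity (ELA)

Six binary components, summed to a 0–6 index: first-year drought (< 200 mm
rainfall), maternal death before age 4, birth into a large group, a
close-in-age younger sibling, a bottom-quartile maternal dominance rank,
and a top-quartile maternal social isolation (the mother's grooming
involvement over the daughter's first two years, computed with the SCI
machinery). Quartile components use type-7 (linear-interpolation) quantiles
computed once over the analysis population; the group-size and interbirth
cutoffs accept fixed literal overrides (>= 36 adults, < 1.5 years) where a
user prefers the conventional values. Tie direction follows each clause:
group size >= threshold, interbirth interval < threshold, maternal rank >=
threshold (rank 1 is highest, so numerically large is low status),
isolation score <= threshold. A female missing any component's inputs is an
error naming the component — the index is only defined for females with
complete information. Females with no younger sibling score 0 on the
close-sibling component (no sibling was born, so none could be close in
age); only the quartile is computed over observed intervals.

## Survival models

Each female enters the risk set at exactly age 4 — cohort membership is
conditional on surviving the juvenile period, making entry a left-truncation
time — and exits at death or administrative censoring. Cox proportional-
hazards fits (lifelines, Efron ties, log-scale Wald CIs) cover a
seven-candidate set crossing cumulative ELA with mean `DSI_paternal`, years
of paternal co-residency, `DSI_non-paternal` and `DSI_all`; optional
interaction models add ELA x paternal terms, and a sixteen-model set
crosses the paternal terms with `SCI_F`/`SCI_M` to ask whether paternal
effects are attenuated by adult connectedness. Comparison is by AICc,

```
AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1),   n = number of subjects
```

with `n` the subject count (an events-based `n` is a defensible alternative;
the function takes `n` explicitly so callers can choose). No multiplicity
correction is applied anywhere — inference is by information-theoretic
comparison.

The proportional-hazards diagnostic is a Grambsch–Therneau scaled-Schoenfeld
test written in-package because the residuals must respect left truncation
(risk set at an event time t is `entry < t <= exit`); the per-term statistic
correlates scaled residuals with rank-transformed event times and the global
row is the corresponding quadratic form. Under proportional simulated data
its p-values are uniform (checked by KS across replicate cohorts), and a
built-in piecewise time-varying effect is detected with high power.

Survival contrasts between covariate profiles use the fitted model's
Breslow-type baseline; the difference of median crossing times is reported,
and a profile whose predicted curve never reaches 0.5 yields an unbounded
(None) contrast rather than a number.

## Behavioural mixed models

Whether a father groomed his daughter in a given year (given >= 30 days of
co-residency) is modelled by binomial mixed models with a father random
intercept over an all-subsets candidate set of eleven predictors (rank,
fertile-female rate, consort-time proportion, sired-previous/next flags,
co-resident offspring years, ELA, juvenile/paternal/maternal ages, observer
effort). Rows missing a consort proportion (mother never observed
consorting at conception — an observation failure, not evidence) or a
sibling paternity are dropped with counts recorded. The co-residency
duration of each father–daughter pair is modelled by linear mixed models
over a nine-term set taken at the month co-residency ended; the
sired-next-offspring flag is excluded because only long co-residencies can
produce future offspring.

Because no installed Python package fits marginal maximum-likelihood
binomial mixed models, the package includes its own random-intercept
logistic fitter: the intercept is integrated out by 25-node Gauss–Hermite
quadrature (the integrals are one-dimensional), the likelihood is maximized
by L-BFGS-B with analytic gradients on an internally standardized design,
and standard errors come from a centered finite difference of the gradient.
The test suite cross-checks coefficients, the random-intercept SD and the
log-likelihood against `lme4::glmer` at matched quadrature accuracy
(`nAGQ = 25`). Linear mixed models use statsmodels `MixedLM`; maximum
likelihood (not REML) is used throughout so AICc comparisons across
fixed-effect structures are valid, with a Powell retry when a boundary
(zero) intercept variance degenerates the profiled likelihood, and an OLS
fallback (flagged `ols_fallback`) when the grouping itself is degenerate.

Candidate sets are enumerated deterministically by subset size and capped
(default 64 models), always retaining the full model. Model averaging is
conditional: Akaike weights `w ∝ exp(-ΔAICc/2)` over the best-supported
subset (top-7 for the grooming model, top-5 for co-residency, mirroring the
table conventions of this literature), each term averaged over the models
containing it, with unconditional standard errors
`sqrt(Σ w (se² + (β - β̄)²))` folding in between-model variance. A
variance-inflation-factor screen (`VIF = 1/(1-R²)`, intercept included in
the auxiliary regressions) guards the candidate designs; on default
simulated covariates all VIFs are well under 2.5.

## The synthetic population

The generator emulates a cohort of 216 juvenile females born into 13 social
groups over a 24-year birth window, with adult censoring mid-2021.

* **Groups** hold stationary rosters of adult males (steady state ~11 per
  group) and females (~20) maintained by Poisson immigration and
  exponential residence times. Because male residence is exponential
  (memoryless, mean 56 months), a father sampled from the males resident
  at a conception has remaining tenure with exactly the configured
  departure hazard — the paternal co-residency distribution falls out of
  the roster process with no special-casing, with an analytic median of
  `(56 x 30.44 x ln 2 - 178) / 30.44 = 33` months of the possible 48
  (gestation is 178 days, so a father departing between conception and
  birth never co-resides; ~10% of females). Departures are deaths with
  probability 0.3, else dispersal.
* **Paternity** is sampled among males resident at conception, weighted by
  a softmax of latent quality (the same quality that orders the monthly
  dominance ranks), so higher-ranking males sire more offspring. Each
  mother also has a previous and (mother surviving, window permitting) a
  next offspring whose paternity is shared with the focal's father with
  probability 0.15 and unknown with probability 0.12, feeding the
  sired-previous/next covariates and their missingness.
* **Grooming** events arise per dyad-year from a Poisson process whose log
  daily rate adds a baseline (log 4e-4), a father increment, an age trend, a
  persistent dyad propensity (SD 0.8), and mating-opportunity terms (rank,
  group fertile-female rate, consort share, co-resident offspring years).
  Observed counts are thinned Bernoulli-per-event with probability
  `min(1, 0.5 x effort)`, where group-year effort declines with log group
  size — this is what makes the observer-effort adjustment in the DSI
  identifiable and testable. Grooming initiation shifts from the male to
  the juvenile with age on a logistic in age (slope 1.0/year).
* **Adversity** components: rainfall is lognormal with P(< 200 mm) = 0.18;
  maternal death in the first four daughter-years has probability 0.18
  (truncated-exponential timing); the four quartile-based components come
  from continuous latent traits and hit ~25% by construction. The resulting
  cumulative distribution has ~20% of females adversity-free.
* **Survival**: adult age at death is drawn from a Weibull baseline (shape
  2.5, scale 21 years; median adult death ~18) conditioned on surviving to
  age 4, multiplied by `exp(eta)` where `eta` loads the female's realized
  adversity count, her standardized true paternal-bond propensity, and her
  realized co-residency years with the default log-hazard coefficients
  log(1.262), log(0.787) and log(0.885). Covariates are centered at
  reference values (ELA 1.4, co-residency 2.4 years) so the baseline keeps
  its scale at a typical female. Administrative censoring at the study end
  leaves ~124 of 216 females censored.
* A **direct cohort generator** (`simulate_cohort_for_survival`) draws the
  survival covariates from their marginal distributions and event times
  from the same hazard, bypassing the behavioural layer; recovery
  experiments for the Cox machinery use it so they are fast and free of the
  full simulator's confounding. `simulate_father_years` plays the same role
  for the logistic models, with raw-scale coefficients
  (0.185 rank, −8.29 fertile rate, 2.334 consort share, …) applied to
  centered covariates.

**Calibration.** The generator's defaults were chosen so that the package's
own analyses, applied to default simulations, reproduce the cohort margins
and effect sizes this literature reports: a ~0.70 father term in the dyadic
bond model, ~20% adversity-free females, a ~33-month median co-residency
and ~124 censored females. In particular the father log-rate increment
(0.55) is a calibrated quantity, not a directly interpretable rate ratio:
the DSI is a z-score, so the increment that yields a 0.70-SD father
contrast depends on the whole residual distribution (floor mass, Poisson
noise, dyad propensity spread).

**What the generator does not emulate.** No group fission/fusion, no
genetics or paternity-assignment error, no infant mortality (the cohort is
conditioned on reaching age 4), no male-male coalitions, no seasonality,
and several bookkeeping simplifications: adult grooming partners are
sampled from the group roster without per-day residency alignment, female
ranks exist only for mothers in their daughters' birth months, and the
behavioural mating-opportunity effects enter through group-level
approximations of the covariates the analysis later measures exactly.
Passing recovery tests therefore demonstrates that the estimators are
correct under the stated model, not that real field data satisfy that
model.

## Numerical choices

* Dates are day-resolution; intervals inclusive; year-of-life windows
  half-open; 29 February birthdays map to 1 March off-leap.
* z-scores use the n−1 standard deviation; degenerate re-standardization
  strata (< 2 females) pass values through with a logged warning so small
  fixtures still run; degenerate z-score strata are errors.
* Quantiles are type-7 everywhere.
* The effort regression needs >= 3 included dyads per stratum and treats a
  constant effort column as slope 0.
* Cox fits require >= 2 events and a full-rank (centered) design; AICc
  requires n > k + 1.
* GLMM optimizer bounds: |standardized coefficients| < 30 (beyond which
  separation is declared), log random-SD in [−6, 3].

## Problem sizes

Recovery experiments use 50 replicates of n = 2000 for the Cox set, 25
replicates of 5000 father-years for the logistic models, 20 default-scale
populations (216 females each) for the calibration margins, and ~1000
randomized mini-fixtures for the day-scan oracles; `scripts/acceptance.py`
re-runs the Cox recovery and the 20-population margins from scratch and
writes the summary quantities as JSON.
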