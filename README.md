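# papiokit

Synthetic primate cohorts and the statistical machinery to ask whether a
juvenile female's early-life relationship with her father predicts her
adult survival.

In many group-living mammals — baboons prominently — fathers provide no
essential care, yet may live and groom with their juvenile offspring.
`papiokit` implements the full analysis pipeline used to study the
long-term consequences of such relationships in longitudinal field data:

* **Dyadic sociality index (DSI).** Each juvenile-female x adult-male
  pair's grooming is converted to a daily rate over co-resident days,
  log-transformed, adjusted for observer effort by regression, and z-scored
  within year-of-life strata. Variants score all co-resident males
  (`DSI_all`), the father only (`DSI_paternal`, including father-absent
  years at the shared zero-grooming floor), and non-fathers. An adult
  analogue (`SCI_F`/`SCI_M`) scores each female's adult connectedness to
  females and males.
* **Cumulative early-life adversity (ELA).** A 0–6 count of drought,
  maternal loss, large group, close-in-age sibling, low maternal rank and
  maternal social isolation, with population-quartile thresholds.
* **Survival models.** Left-truncated Cox proportional-hazards models (risk
  entry at age 4, exit at death or censoring) over a seven-candidate set
  combining ELA with the paternal covariates, compared by AICc; ELA x
  paternal interaction models; adult-connectedness mediation models;
  scaled-Schoenfeld proportional-hazards diagnostics that respect left
  truncation; median-survival contrasts between covariate profiles.
* **Behavioural mixed models.** Binomial mixed models (own marginal-ML
  random-intercept fitter, validated against `lme4::glmer`) of whether a
  father grooms his daughter, linear mixed models of co-residency duration,
  all-subsets AICc candidate sets, Akaike-weight model averaging, and a VIF
  collinearity screen.
* **A synthetic-population generator** producing all input tables
  (individuals, residencies, grooming events, ranks, effort, rainfall,
  consortships, ovulation windows) with known ground truth, so every stage
  above has a parameter-recovery oracle. A direct covariate-level cohort
  generator supports fast recovery experiments for the survival and
  logistic models.

## Worked example

Draw a cohort of 2,000 females directly from the default hazard
configuration and compare the seven candidate survival models:

```python
from papiokit import SimulationConfig, simulate_cohort_for_survival
from papiokit.survival import run_model_set, survival_contrast

rec, truth = simulate_cohort_for_survival(SimulationConfig(), 2000, seed=1)
comp = run_model_set(rec)
print(comp.table().round(2).to_string(index=False))
```

```
model   loglik  k    n     aicc  delta_aicc
    A -5419.00  3 2000 10844.02        0.00
    B -5440.64  2 2000 10885.28       41.26
    D -5440.44  3 2000 10886.90       42.88
    C -5442.78  2 2000 10889.57       45.56
    E -5465.25  1 2000 10932.49       88.48
    G -5465.12  2 2000 10934.24       90.22
    F -5465.14  2 2000 10934.30       90.28
```

Model A — adversity + mean paternal DSI + years of paternal co-residency —
is the generating structure and wins decisively at this sample size. Its
hazard ratios recover the generator's truth (1.262, 0.787, 0.885):

```python
print(comp.fit("A").summary().round(3))
```

```
                    coef     se     hr  hr_lower  hr_upper
ela                0.254  0.033  1.289     1.210     1.374
mean_dsi_paternal -0.243  0.036  0.784     0.731     0.841
coresidency_years -0.144  0.022  0.866     0.830     0.904
```

Per unit: each adversity source raises mortality hazard ~29%, each SD of
paternal bond strength lowers it ~21%, each co-resident year ~13%. The
predicted median-survival gain for a female at the top versus bottom
paternal-DSI quartile (±0.67 SD, other covariates fixed) is about 2.3
years:

```python
lo = {"ela": 1.0, "mean_dsi_paternal": -0.67, "coresidency_years": 2.0}
hi = {"ela": 1.0, "mean_dsi_paternal": 0.67, "coresidency_years": 2.0}
survival_contrast(comp.fit("A"), lo, hi)   # 2.34
```

The full behavioural pipeline — simulate a 216-female population, compute
DSI/ELA/SCI, fit every model set, write report tables — runs as

```sh
papiokit run --seed 7 --out results/run7
```

producing `dyad_years.csv`, `female_summaries.csv`, `ela.csv`, `sci.csv`,
`survival_records.csv` and the four report tables (`table1_analog.csv` …
`table4_analog.csv`) plus a provenance manifest. Identical config and seed
reproduce every report byte-for-byte. See `docs/methods.md` for the model
and generator details.

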