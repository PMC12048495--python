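# suipath

Propensity matching, from-scratch causal estimators and
inverse-correlation network pathway analysis for two-arm treatment
cohorts.

The package is built around a concrete clinical question: in elite female
athletes with severe stress urinary incontinence (SUI), does adding
non-ablative Er:YAG laser therapy (VEL+UEL) to pelvic floor muscle
training (PFMT) improve one-year dryness and return to elite sport?
Answering that from observational data requires a chain of methods, and
`suipath` implements each link as reusable, tested code:

- **Synthetic cohorts** — a Gaussian-copula generator that reproduces the
  study's per-arm variable moments and association structure, with
  configurable treatment effects, so the full analysis runs and is
  testable without any patient data.
- **Propensity-score matching** — Newton–Raphson logistic PS model,
  greedy one-to-one nearest-neighbor matching within a caliper of 0.2 SD
  of the PS logit, SMD balance diagnostics, and a covariate-set
  sensitivity resampler (50 random sets of 4 covariates).
- **Causal estimators** — multivariate logistic regression, VIF
  diagnostics, IPTW (weights 1/e and 1/(1−e)), instrumental-variable
  2SLS, difference-in-differences, and model-fit statistics
  (adjusted R², F) — all written against plain numpy normal equations.
- **Variable network** — Pearson correlation matrix → undirected graph
  with edge weights 1/|r| (strong associations = short edges), VIF-scaled
  node sizes, period colors, node pruning and deterministic spring
  layout, exported as GraphML/TSV.
- **Treatment pathways** — Dijkstra shortest paths with deterministic
  tie-breaks, waypoint-constrained paths, severity branch rules that
  stratify patients by the route their profile implies, per-stratum cure
  rates, a natural-cure estimate and binomial cure-rate comparisons.
- **Pipeline** — one config, one seed, byte-reproducible report bundle;
  also available as a thin CLI (`suipath run`, `simulate`, `match`,
  `sensitivity`, `estimate`, `network`, `pathways`, `report`).

## The core quantities

For treatment indicator T, outcome Y and covariates X:

- propensity score `e(X) = P(T=1 | X)`; matching on `logit e(X)` within a
  caliper of 0.2·SD; balance judged by SMD < 0.1;
- IPTW contrast `Σ wT·Y/Σ wT − Σ wC·Y/Σ wC` with `w = 1/e` or `1/(1−e)`;
- 2SLS: regress T on instrument Z, then Y on the prediction — consistent
  under unobserved confounding if Z is valid;
- DiD: `(post−pre | T=1) − (post−pre | T=0)`, equal to the interaction
  term of the two-way regression;
- VIF `= 1/(1−R²)` for multicollinearity screening;
- network edge weight `= 1/|r|`, so Dijkstra finds chains of strong
  correlations;
- natural-cure arithmetic: `round(rate·n, 2)` expected spontaneous cures,
  then the percentage of the group that represents.

## Worked example

`examples/04_causal_estimators.py` injects a known treatment effect of
42.154 pad-test points into a structural benchmark and asks each
estimator to recover it under its own identifying assumption:

```
truth                 : 42.154
naive arm difference  :  49.115  (biased by observed confounding)
IPTW                  :  41.852 ± 0.341
IV / 2SLS             :  41.567 ± 0.766  (first-stage F = 1561)
DiD (on improvements) :  42.023 ± 0.355
```

The naive contrast overshoots by ~7 points because treated patients have
systematically different covariates; each adjusted estimator lands within
a few standard errors of the truth.

`examples/06_treatment_pathways.py` stratifies a simulated cohort by the
severity branch rule (bladder neck descent above the cohort mean routes
the patient through node `af`) and prints, per stratum, its share of the
cohort and one-year dryness rate, followed by the natural-cure estimate —
e.g. at a 25.2% control-arm spontaneous cure rate, 42.59 of 169
mild-severity treated patients (25.2%) would be expected to recover
without treatment — and a cure-rate comparison (z = 20.73, exact
p ≈ 5e-207 on that simulated cohort).

The other examples cover cohort simulation, matching balance, the
sensitivity resampler, the variable network, and the end-to-end pipeline;
each prints what it computes and what the numbers mean.

## Layout

```
src/suipath/        catalog, simulate, matching, estimators, network,
                    pathways, pipeline, cli
examples/           one narrative script per capability
tests/              unit, property and acceptance tests
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
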