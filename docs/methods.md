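# Methods

`suipath` analyses a two-arm observational treatment comparison — modelled
on a cohort of elite female athletes with severe stress urinary
incontinence (SUI), where the treated arm received vaginal/urethral
non-ablative Er:YAG laser therapy (VEL+UEL) on top of pelvic floor muscle
training (PFMT) and the control arm PFMT alone.  Every stage is generic:
a cohort table with short variable codes, propensity matching, a suite of
causal estimators, an inverse-correlation variable network, and
shortest-path patient stratification.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Variable catalog

Variables are addressed by short codes `a` … `bj` (62 in total).  Each
catalog entry carries a name, a study period (1 = baseline, 2 = three-month
follow-up, 3 = one-year follow-up), a measurement type, and per-arm target
moments: mean/SD for continuous variables, prevalence for binary ones.
Notable structural choices:

- **Aliases.** Several codes are duplicate labels for the same quantity
  (`p`/`ai` testosterone, `k`/`an` PFMT frequency, `be`/`bi` dryness,
  `bf`/`bj`/`j` return to sport, `o`/`bh` and `aj`/`bg` improvement flags).
  Aliases are generated as exact copies of one canonical column, so the
  analysis is consistent no matter which code is referenced.
- **Milestones.** `ap` (initial assessment) and `av` (three-month
  follow-up) are modelled as continuous composite severity scores rather
  than constant marker flags: a constant column has no defined correlation
  with anything and would leave the assessment timeline disconnected in
  the network.
- **Constant columns.** Some variables have no variability by design
  (e.g. vaginal delivery = 1 for everyone, several zero-prevalence
  comorbidities).  They are generated as constants, flagged, and must flow
  through every stage without crashing — real cohort tables contain such
  rows, where a p-value simply cannot be computed.
- A handful of codes have no printed label; they carry inferred names
  marked "(inferred; unlabeled code)" and neutral moments.

## Synthetic cohort generator (Gaussian copula)

`generate_cohort` draws a latent multivariate normal `Z ~ N(0, R)` via the
Cholesky factor of the target correlation matrix, then maps each margin:

- continuous code: `x = mean_arm + sd_arm * z`;
- binary code: `x = 1{Phi(z) < prevalence_arm}` (quantile thresholding).

`R` is assembled from a sparse dictionary of code-pair entries; the default
entries encode the reported pairwise association structure (testosterone
positively and total cholesterol negatively associated with return to
sport, pelvic-floor contractility tied to pad-test severity, a strong
`ap`→`av` assessment chain) with all other off-diagonals zero.  The result
is repaired to positive semi-definiteness by eigenvalue clipping
(eigenvalues floored at 1e-6, then re-normalised to unit diagonal); a
non-PSD matrix with repair disabled is an error.  Entries involving binary
codes live on the latent (tetrachoric-like) scale.

Outcomes are structural, not copula margins:

- **Binary one-year outcomes.** Dryness `bi`:
  `logit P = intercept + Σ βc·x̃c + Δ·treat` with `Δ` the configurable
  log-odds treatment effect (default 3.2, anchoring a ≈0.29 control vs
  ≈0.91 treated dryness rate).  Return to sport `bj` depends on treatment
  through `bi` plus a direct term.  Continuous predictors enter
  standardized; binary predictors raw.  Bernoulli draws share one uniform
  per patient across both potential arms, so exact potential outcomes
  (`p0, p1, y0, y1`) are stored on the cohort and the injected average
  treatment effect can be audited against a brute-force potential-outcomes
  average.
- **Continuous improvements.** One-year pad-test improvement
  `Δpad = 32.78 + Σ βc·x̃c + 42.154·treat + ε` (grams; control-arm
  intercept and treated–control contrast anchored to the study's reported
  improvement levels, noise SD 12) and ICIQ-SF improvement
  `ΔICIQ = 1.66 + … + 10.78·treat + ε` (score points, noise SD 3.5).
  Follow-up columns are derived from them: `n = ao − Δpad`,
  `m = i − ΔICIQ`, three-month values at 60% of the one-year improvement,
  and the binary improvement flags `bh`, `bg` as `Δ > 0`.  The additive
  form makes the true pad-test ATE exactly the configured effect.

Identical `(spec, catalog, seed)` give byte-identical tables (single
`numpy` Generator, fixed draw order; CSVs are re-read with round-trip
float parsing).

What the generator does **not** emulate: longitudinal dropout, missing
data, floor effects (a large improvement can push a follow-up pad test
below zero), measurement error models, and the reported severity
interaction in which severe cases cure at a *higher* rate under treatment.
Passing tests therefore demonstrate correctness of the machinery under a
clean data-generating process, not clinical validity on real data.

## Causal benchmark generator

The copula cohort describes two arms conditionally, so it has no
treatment-assignment mechanism and no instrument.  Estimator validation
uses `generate_causal_benchmark`: confounders `x1, x2 ~ N(0,1)`, an
unobserved `u`, a randomized-encouragement instrument `z ~ Bernoulli(0.5)`,
treatment assigned by a logistic model in `(x1, x2, u, z)` with a
`treated_fraction` intercept, and an improvement
`y = 30 + t·(x1+x2) + 5·γu·u + effect·treat + ε` with `pre − post = y`.
The constant additive `effect` makes the true ATE known exactly.  Each
estimator is validated under its own identifying assumption:

| estimator | condition | knob |
|---|---|---|
| IPTW / matching | observed confounding only | `confounding > 0`, `unobserved = 0` |
| IV (2SLS) | unobserved confounding + valid instrument | `unobserved > 0`, `instrument_strength` large |
| DiD | level-only confounding (parallel trends) | `trend_confounding = 0` |

No estimator can be expected to recover the effect outside its assumption
(DiD is inconsistent when confounders shift the improvement itself), and
the tests deliberately do not ask it to.

## Propensity matching

The propensity model is a hand-written Newton–Raphson logistic regression
(step-halving, log-likelihood tolerance 1e-8, at most 100 iterations; SEs
from the inverse observed information).  Zero-variance covariates are
dropped with a warning; perfect separation (every fitted probability
numerically equal to its label with diverging coefficients) raises an
error advising covariate removal.

Matching is greedy one-to-one nearest-neighbor without replacement on the
PS logit, inside a caliper of `0.2 × SD(logits)` (sample SD, ddof = 1).
Treated subjects are processed in descending-logit order with row-id
tie-breaks, and among equidistant controls the smallest id wins, so the
matched sample is a pure function of the data.  Balance is summarized by
the standardized mean difference
`|mean_t − mean_c| / sqrt((var_t + var_c)/2)` with `p(1−p)` variances for
binary covariates; zero pooled variance yields 0 for equal means and an
infinity flag otherwise.  One-to-one matching needs a control reservoir to
balance against: with 50/50 arms the nearest available control is
systematically offset, and residual SMDs around 0.1 remain even with a
correct PS model; with a study-like 1:3 treated:control ratio post-match
SMDs fall well below the 0.1 convention.

**Covariate-set sensitivity.**  `covariate_set_sensitivity` draws `n_sets`
(default 50) random sets of `set_size` (default 4) covariates from a pool,
refits the PS, rematches, and records the matched difference in an outcome
— by default the one-year ICIQ-SF improvement (`i − m`), whose matched
contrast sits near 11–13 score points under the default generator.  Sets
are sampled without replacement within a set, independently across sets;
sets yielding zero matches or a separated fit are recorded as missing and
excluded from the mean/SD (ddof = 1).  One caveat documented here because
it matters for interpreting the spread: the 50 effects are computed on one
cohort and share its outcome noise, so they are positively correlated
across sets; the cross-set SD describes sensitivity to covariate choice,
but `SD/√50` is *not* a standard error for the mean effect.

## Estimators

All estimators are plain numpy linear algebra; Wald inference
(`CI = estimate ± 1.96·SE`) throughout.

- **Logistic regression** — as above; Wald p-values from the normal.
- **VIF** — `VIF_j = 1/(1 − R²_j)` from regressing each variable on the
  others plus a constant (centered R²); the constant term's own VIF
  (uncentered R²) is reported in a separate row, matching the standard
  design-matrix convention.  `1 − R² < 1e-10` is flagged infinite rather
  than raised.
- **IPTW** — weights `1/e` (treated) and `1/(1−e)` (control); estimate is
  the difference of weighted means; SE is the robust weighted form
  `Σ w²(y−μ̂)² / (Σ w)²` summed over arms.  Scores exactly 0/1 are an
  error unless truncation (clip to [0.01, 0.99]) is requested; truncation
  is off by default.
- **IV / 2SLS** — stage 1 OLS of treatment on the instrument, stage 2 OLS
  of outcome on predicted treatment; SEs use the 2SLS residual (observed
  treatment at the 2SLS coefficients).  The single-instrument first-stage
  F (= t² of the stage-1 slope) is reported and a value below 10 warns of
  a weak instrument.  With the instrument identical to treatment, 2SLS
  collapses to OLS to machine precision.
- **DiD** — the four-mean arithmetic
  `(post−pre | treated) − (post−pre | control)`, recomputed as the
  interaction coefficient of the stacked two-way regression and asserted
  equal to 1e-10; the regression supplies the SE.
- **Model fit** — `adj R² = 1 − (1−R²)(n−1)/(n−p−1)`; overall F with
  `(p, n−p−1)` degrees of freedom; requires `n > p + 1`.

## Variable network

Pairwise-complete Pearson correlations over all cohort columns (constant
columns get undefined entries, flagged not raised; fewer than 3 rows is an
error).  The graph has an edge `(i, j)` iff `r_ij` is defined and
`|r_ij| ≥ min_abs_r`; its weight is `1/|r_ij|`, so a short path is a chain
of strong associations.  `min_abs_r` defaults to 0.05: inverse weights
diverge as `r → 0`, and a floor both avoids near-infinite edges and drops
sampling noise (at n = 82, |r| ≈ 0.05 is well inside noise; the floor is a
display/graph-sparsity choice, not a significance test).  Node colors are
period tags (`skyblue`/`lightgreen`/`lightcoral` applied at export); node
sizes are `base × max(VIF, 1)` for highlighted variables — by default the
five model variables with their fitted-model VIFs (treatment ≈ 3.0,
testosterone ≈ 2.8, PFMT frequency ≈ 1.7, core training ≈ 1.1,
T-cho ≈ 1.2) — and `base` otherwise.

Pruning has two modes: an explicit list (default: the ten standard
exclusions `y, t, ad, ae, v, e, ac, f, ab, u`) and a reusable threshold
mode that removes isolated nodes and nodes farther than a weighted-distance
cutoff from the milestone set.  Milestones can never be pruned, and
pruning never alters surviving edge weights.

Layout is Fruchterman–Reingold with a fixed seed.  Disconnected components
are laid out independently, normalized to unit radius, and tiled on a grid
(spacing 5): a single spring layout can interleave unrelated components,
which misrepresents the graph structure.

## Pathways

Shortest paths use Dijkstra with a deterministic tie-break: the heap is
ordered by `(total weight, node sequence)`, so among equal-weight paths the
lexicographically smallest node sequence wins.  Near-ties are resolved with
an absolute tolerance of 1e-12.

Waypoint-constrained paths (`required` ≤ 4 nodes, `forbidden` removed up
front) evaluate every permutation of the required nodes and concatenate
segment-wise shortest paths; the minimal total weight wins with the same
tie-break.  Segment concatenation can revisit nodes — such walks are
permitted but flagged (`revisits`), since requiring a *simple* path
through a node set is NP-hard and the additive reading ("the route also
includes the treatment node") matches the clinical narrative.

`assign_paths` stratifies patients: the milestone sequence
`ap → av → bi → bj` fixes the endpoints and always-required interior
waypoints; branch rules (e.g. "bladder neck descent above the cohort mean
⇒ route through `af`") insert extra required nodes per patient.  "Above
average" is strictly greater than the cohort mean; boundary equality takes
the bypass branch.  Patients are grouped by their resulting node sequence,
and each stratum reports size, cohort share, and one-year dryness rate.

**Natural-cure arithmetic.**  `natural_cure_estimate(rate, n)` computes
`expected = round(rate·n, 2)` first and then
`pct = round(100·expected/n, 2)` — the round-then-divide order is part of
the contract (0.2889 over 23 patients gives 6.64 expected cures = 28.87%,
not 28.89%).  **Cure-rate comparison** returns both the pooled
two-proportion z statistic (sign: treated minus control) and the exact
binomial tail of the treated count under the control rate (upper tail when
the treated rate is at least the control rate), because with small strata
either convention is defensible.

## Pipeline

`run_pipeline` executes simulate/load → match → sensitivity → estimators →
network → pathways → report from one validated config (unknown keys
rejected).  A single global seed is split through `numpy.SeedSequence`
into per-stage seeds, so one integer reproduces the whole run; all tables
are TSV with headers and all structured outputs JSON, so runs diff
cleanly.  The pathways stage requires the network stage; IV runs only when
an instrument column is configured, since no catalog variable is an
instrument.  The default configuration uses the matched-study arm sizes
(41 + 41); validation tests use larger cohorts (2000–5000 per arm) where
moment and recovery checks have usable power, and the path-oracle checks
use 8-node random graphs where exhaustive enumeration is feasible.

## Known limitations

- Follow-up scores derived from large improvements can be negative; no
  floor is applied so that the additive effect stays exact.
- The inverse-correlation weighting makes long chains of strong edges
  compete with weak direct edges; which wins depends on the correlation
  regime, and on dense sample-correlation graphs the data-driven shortest
  path need not pass through the nominal milestones.
- Greedy matching is not optimal matching; it is the deterministic,
  standard variant of nearest-neighbor caliper matching.
- Wald inference everywhere; no profile-likelihood or bootstrap CIs.
- Marginal Pearson correlations only; no partial-correlation network.
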