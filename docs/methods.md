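# Methods

This note documents the statistical models, algorithms, numerical
conventions and design choices behind `ypstage`, in the spirit of the
model documentation that simulation and survival packages ship with
their code. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

Post-neoadjuvant pathologic (yp) staging classifies oesophageal-cancer
patients after neoadjuvant radio(chemo)therapy and resection from three
specimen-level inputs: the residual tumour depth category
(ypT0–ypT4b), the count of pathologically positive regional lymph
nodes, and the tumour regression grade (TRG, CAP/modified-Ryan scale
0–3). A staging system is a total mapping from these inputs to an
ordered set of stage labels. The package builds and validates a
modified system in which the nodal component is re-cut from the data
(0 / 1–2 / ≥3 positive nodes instead of the AJCC 0 / 1–2 / 3–6 / ≥7)
and TRG enters as a staging element, and compares it head-to-head with
the eighth AJCC yp system.

## Synthetic cohort generator

Patient-level data behind the published analysis are not deposited, so
all pipeline stages are exercised on synthetic cohorts
(`ypstage.cohortgen`).

**Covariates.** ypT category, positive-node count and collapsed TRG
group are drawn independently from the published marginal frequencies:
ypT (T0…T4b) = 107/46/119/181/24/9 out of 486; node counts 70.4%,
13.4%, 6.2% for 0/1/2, then 3.5/1.0/1.4/0.6% for 3–6, and the
remaining 3.5% (≥7 nodes) spread geometrically (ratio ½) over 7–12;
TRG 0–1 / 2 / 3 = 213/173/100 out of 486. The published report also
states a slightly different TRG percentage breakdown in its text
(43.4/36.0/20.6); the generator follows the baseline-table counts. The
joint distribution is not published, so independence is the default; a
real cohort would show positive dependence between residual depth,
nodal burden and poor regression, which the generator does not emulate
— tests that pass on it validate the machinery, not the biology of any
particular cohort. Sex (81.9% male), concurrent chemotherapy (30.7%)
and radiation dose (≤40 vs >40 Gy, 73.9/26.1%) are generated for the
screening workflow and carry no hazard effect by default.

**Survival model.** Event times follow a piecewise-exponential model:
baseline hazard λ_j per month on intervals cut at 0, 12, 36, 60 months
(the last rate extends indefinitely), multiplied per patient by
exp(β_T + β_N + β_G), the summed log hazard ratios of the ypT group,
the node-count group and the TRG group. Defaults:

| effect | groups | log HR |
|---|---|---|
| ypT | T0/T1/T2, T3, T4a, T4b | 0, 0.5, 0.9, 1.4 |
| nodes | 0, 1–2, ≥3 | 0, 0.55, 1.10 |
| TRG | 0–1, 2, 3 | 0, 0.5, 0.9 |

Two features are deliberate: the nodal hazard is *flat above three
positive nodes*, so the true prognostic grouping of node counts is the
three-level one the partitioning stage should find (and the AJCC N2/N3
split is pure noise); and TRG carries independent prognostic
information that a T/N-only system cannot use. Magnitudes are in the
range of published multivariable hazard ratios for these factors
(≈1.6–4 per step).

**Calibration.** `calibrate_baseline` solves for the rates λ_j
sequentially by Brent root-finding so that the *covariate-averaged*
survival S̄(t) = Σ_k P(k)·exp(−HR_k·Λ₀(t)) equals the published
anchors S(12) = 0.842, S(36) = 0.553, S(60) = 0.456 exactly
(analytically, before sampling noise). Each equation is monotone in
one rate, so the solution is unique; infeasible (non-decreasing)
anchors raise a calibration error. With three anchors the implied
median OS is ≈46–49 months against a published 43.7 — a
piecewise-constant hazard on three intervals cannot match a fourth
quantile, and the anchors take priority.

**Censoring.** Accrual is uniform over 132 months with a fixed
administrative cutoff at 150 months (an 11-year accrual window
followed through ~1.5 further years, matching a median potential
follow-up of the order of the published 62 months). Censoring is
therefore independent of covariates by construction. No loss to
follow-up, recurrence, or competing risks are modelled.

**Engineered cohorts.** Two auxiliary builders support the recovery
tests: `generate_subgroup_cohort` plants an exponential hazard per
T×N×TRG cell, and `deterministic_cell_cohort` places each cell's
observations at the exact mid-probability quantiles of its exponential
distribution (uncensored), so cells sharing a hazard have *identical*
empirical curves. The latter is used where a known merge pattern must
be forced without sampling noise.

## Survival-statistics core

All estimators and tests (`ypstage.survstats`) are implemented from
first principles; the test suite cross-checks them against independent
brute-force oracles and against lifelines.

* **Kaplan–Meier** product-limit estimator with Greenwood variance.
  At tied observed times deaths precede censorings (censored subjects
  remain at risk at their own time). `survival_at` evaluates the
  right-continuous step function; querying beyond the last observed
  time carries the last value forward and flags extrapolation.
* **Log-rank test**: per-event-time hypergeometric observed−expected
  contributions with the full covariance (ties handled by the
  (N−d)/(N−1) factor); χ² from the first G−1 groups via a linear
  solve, df = G−1.
* **Linear-trend log-rank**: U = Σ_g s_g(O_g−E_g) with variance
  sᵀVs over the same covariance; df = 1. Default scores are the group
  ranks 0…G−1 (the published analyses treat stages as ordinal with no
  stated scores); the statistic is invariant to affine score
  transforms and reduces to the ordinary log-rank χ² for G = 2.
* **Cox partial likelihood**: Newton–Raphson with step-halving,
  convergence when max|score| < 1e-8 or the relative log-likelihood
  change < 1e-10. Ties use the Efron correction by default (Breslow by
  flag) — the published analysis does not state its choice and Efron
  is the better approximation; exact replication invariance under
  subject duplication holds for Breslow only. Monotone likelihood is
  detected by a scale-aware divergence check (|β|·sd(x) > 15, i.e. a
  hazard ratio above e¹⁵ per covariate standard deviation) and raises
  an error naming the covariate; a singular information matrix raises
  a rank error. The likelihood-ratio χ² is 2(ℓ̂−ℓ₀) and
  AIC = −2ℓ̂ + 2p.
* **Harrell's c**: pairs are comparable when the shorter observed time
  is an event and strictly shorter; equal event times are not
  comparable; score ties count ½. No clamping — a perfectly
  anti-predictive score yields c = 0.
* **Proportional-hazards check**: Grambsch–Therneau global test —
  Schoenfeld residuals at each event correlated with a centred time
  transform (default 1 − KM(t), with identity and rank transforms
  available), statistic d·uᵀI⁻¹u / Σ(g−ḡ)², χ² with one df per
  covariate.
* **Time-dependent AUC**: IPCW cumulative-case/dynamic-control
  estimator. Cases at horizon t (event by t) are weighted 1/G(T−),
  controls (under observation past t) 1/G(t), with G the Kaplan–Meier
  estimate of the censoring distribution; grid points without cases or
  controls are flagged undefined rather than raising. Reported
  standard errors are a Hanley–McNeil approximation with effective
  (weighted) group sizes — descriptive only. Between-system AUC
  differences are tested with a paired nonparametric bootstrap
  (default 1000 resamples, seeded; subjects resampled, censoring KM
  and both AUCs recomputed per resample; two-sided p as twice the
  smaller tail, so identical scores give p = 1). An
  influence-function variance would be the analytic alternative; the
  bootstrap was chosen because it is simple to verify by simulation.

## Nodal reclassification (survival tree)

`NodeCountPartitioner` is a scikit-learn style estimator (`fit(X, y)`,
`predict`, `get_params`) that grows a binary survival tree over a
single integer covariate — here the positive-node count. Splits
maximise the two-group log-rank χ² over every integer threshold
between observed distinct values (LeBlanc–Crowley style; deviance-based
splitting would be the CART alternative, but log-rank splitting matches
the log-rank-centric evaluation downstream). Because the selected
statistic is maximal over candidates, its p-value is Bonferroni-
adjusted over the number of admissible thresholds by default; growth
stops when no admissible split exists, the adjusted p ≥ α, the depth
limit is reached, or a child would fall below the leaf minimum.
Defaults min_leaf = 20, α = 0.05, max_depth = 3 keep the cohort-scale
problem (n ≈ 500, ≤13 distinct counts) tractable and make the
three-leaf solution reachable. Leaves always tile [0, ∞) with
contiguous integer intervals and are emitted as a reusable nodal
mapping (`leaves_to_groups`). Missing counts are a schema error; there
are no surrogate splits and no cost-complexity pruning.

## Subgroup merging

`build_subgroups` crosses the WECC yp tumour groups (T0-2, T3, T4a,
T4b) with a nodal mapping (tree-derived or the published 0 / 1–2 / ≥3)
and the collapsed TRG (0–1, 2, 3). T4b forms a single cell, never
subdivided, and is *pinned*: it bypasses the merge and is assigned the
final (worst) stage group, mirroring the rule that T4b disease is
highest-stage for any nodal status or regression grade.

Cells are ordered best-to-worst by 5-year Kaplan–Meier OS (median
survival breaks ties) and merged agglomeratively under the 0.15
log-rank threshold; only adjacent clusters on the risk order may
merge, which keeps stages ordinal. The merge criterion is the largest
*cell-level pairwise* log-rank p across the cluster boundary: while
any adjacent pair of clusters contains a cross-boundary cell pair with
p ≥ 0.15, the pair with the largest such p merges. The natural
alternative — a pooled two-group test between clusters, recomputed
after each merge — was implemented (`method="pooled"`) and rejected as
the default: clusters are formed by sorting cells on their *observed*
survival, so a pooled contrast between the lower and upper part of
that sorted order is systematically anti-null (the selection bias does
not shrink with sample size), and identical-hazard cells then fail to
merge at rates far above nominal. Cell-level tests are computed once,
between cells defined a priori, and remain calibrated. Cells with
fewer than two subjects are excluded from testing, flagged, and
attached to the risk-nearest cluster. Under this convention the
no-merge limit is threshold → 1, and lower thresholds produce coarser
partitions (merging only becomes easier as the bar drops).

The merge trace (which clusters pooled, at what p) is recorded and can
be replayed to the final assignment. `assemble_system` turns the
assignment into a total staging system: domain cells unseen in the
cohort inherit the group of the nearest observed cell in
(T rank, N rank, TRG rank) lexicographic distance and are flagged;
one merged group is an error (a staging system needs ≥2 labels).
Stage labels are applied in risk order, worst last.

## Evaluation framework

`score_system` computes, per staging system on one cohort: the
linear-trend log-rank χ² across observed stage groups (monotonicity),
the likelihood-ratio χ² and AIC of a Cox model on stage indicator
variables with the lowest observed stage as reference (homogeneity and
parsimony-adjusted fit), and Harrell's c (discrimination). The risk
score for c and the AUC curves has two modes: the Cox linear predictor
on stage indicators (default, the common practice in staging
comparisons) or the raw ordinal rank; reports record the mode.
Stage labels with no members are dropped from the design with a
record; a system observed as a single group cannot be scored.
`compare_systems` adds IPCW AUC curves on a common grid (default
12–60 months in 12-month steps, matching yearly reads) and
paired-bootstrap p-values at requested times, and serialises
everything to JSON with a full configuration echo.

The univariable→multivariable workflow (`univariable_screen`,
`multivariable_fit`) screens categorical factors by log-rank at
p < 0.05, then fits one Cox model with indicator coding (reference =
most frequent level), reporting hazard ratios with 95% Wald intervals
and the proportional-hazards global test. The published covariate
coding (reference levels, dose dichotomised at 40 Gy) is not fully
specified; the baseline-table binary splits are used as the default
factor set, and this is a reconstruction.

## Problem sizes and stochastic test design

Simulation-based tests fix every seed and state their conditions in
the test body. The main choices:

* Type-I-error calibrations: 400 replicates (log-rank at n = 150,
  proportional-hazards test at n = 300 — the larger n because the
  Grambsch–Therneau test is asymptotic), acceptance band [0.03, 0.08]
  at α = 0.05.
* Cut-point recovery: hazard steps of ratio 3 planted at 1 and 3
  positive nodes, n = 2000, 100 replicates, ≥90% exact recovery.
* Merge recovery: rate ratios 1:2:4 planted across the full 27-cell
  T×N×TRG domain, n = 3000 (111 per cell), 100 replicates, ≥90%
  exact three-group recovery. With only two or three cells per hazard
  level the pairwise criterion has a single shot at each boundary and
  recovery drops — an inherent property of thresholding uniform null
  p-values at 0.15, not an implementation defect.
* Directional comparison: 50 replicates at n = 2000 under the default
  generator; the modified system must beat the AJCC system on all
  four metrics in ≥90% of them. The published patient-level values
  (e.g. trend χ² 127.5 vs 80.3 at n = 486) are not reproducible
  without the original cohort; direction, not magnitude, is the
  testable claim.
* `scripts/acceptance.py` uses n = 5000 for the survival anchors and
  n = 2000 for the staging comparison, with 1000 bootstrap resamples
  for the 3-year AUC contrast.

## Known limitations

* Covariate independence in the generator (see above); real cohorts
  correlate depth, nodal burden and regression grade, which would
  strengthen the modified system's observed advantage but also change
  subgroup sizes.
* The merge procedure explores only adjacent clusters on the risk
  order and has no bootstrap stability analysis; alternative tumour
  groupings are not searched.
* The AUC comparison p-value is a bootstrap quantity with resolution
  1/n_boot; the analytic influence-function variance is an extension
  point.
* No competing risks, recurrence modelling, frailty or time-varying
  covariates; interval censoring is out of scope.
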