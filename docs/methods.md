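# Methods

## Estimand and outcome definition

The pipeline estimates, per therapy arm and follow-up window, the 4×4
matrix of probabilities of moving from the baseline IGA severity stage to
the stage observed in that window. Stages collapse the 5-point IGA scale:
IGA 0 and 1 are one stage ("clear / almost clear"), IGA 2, 3, 4 each their
own. Both windows are referenced to baseline — the 1–12-month matrix is a
baseline→window estimand, not a month-1→month-12 chain.

A window's outcome is the binned IGA of the **last** visit inside it
(earlier visits are ignored when they disagree). Patients without a visit
in the window are imputed by last observation carried forward: the first
window carries the baseline stage; the second carries the first window's
outcome. LOCF makes the outcome total, so every row denominator is full,
at the cost of biasing matrices toward the identity as follow-up
missingness grows; the LOCF-totality test demonstrates the limiting case
(no visits at all ⇒ identity matrix exactly). Windows are (0, 30] and
(30, 365] days (one month = 30 days).

## Matching

Therapy choice is confounded with severity, so matrices are estimated on a
matched pseudo-population. Every patient anchors one triple: itself plus
its Mahalanobis-nearest neighbor in each of the two other arms, *with
replacement*. The matching vector holds 17 baseline covariates — sex, age,
employment, marital status, education, smoking, disease duration, family
history, four lesion-site indicators, PASI, BSA, DLQI, comorbidity, and
the baseline stage as an ordinal 0–3 code; binary covariates enter as 0/1.
BMI is recorded but deliberately not matched on. The metric covariance is
estimated once on the pooled completed data (ridge-repaired if singular);
ties break toward the lowest patient id, so matching is deterministic.
Matching runs independently inside each imputed data set, each with its
own covariance.

Therapy T's estimate then uses every triple's T-slot unit with frequency
weights (the number of triples the unit appears in). Each therapy
population thus has exactly one representative per triple, so the three
populations have identical size and comparable covariates by construction;
"overall" pools the three. Cell variances are binomial, p(1−p)/n_row with
the weighted denominator — the simplest estimator consistent with the
scale of the published interval widths — and are isolated behind one
function so a design-based alternative can be swapped in. Structural zero
or one cells get variance 0. Rows whose weighted denominator is zero are
reported as undefined (NaN), never silently zeroed.

Balance diagnostics report, per covariate and pairwise arm contrast, the
absolute standardized mean difference (denominator: pre-matching pooled SD
of the two arms, for pre and post alike) and a two-sample test — Welch's
t for continuous covariates, χ² for binary — the post-matching test run on
the weight-expanded samples. With-replacement expansion reuses units, so
post-matching p-values are anticonservative and the SMD is the diagnostic
to trust. Under realistically strong confounding, nearest-neighbor
matching in 17 dimensions shrinks severity SMDs substantially (typically
0.3–0.8 → 0.1–0.25) but regresses toward the donor-pool mean; residual
imbalance above 0.1 against the biologic arm is expected at a few thousand
patients and is a property of the design, not a defect of the search
(which is tested cell-exactly against brute force).

## Multiple imputation

Baseline covariates carry 1.5–8.1% missingness; therapy and baseline stage
are always observed. Missing covariates are completed by chained
equations: continuous variables by predictive mean matching (Bayesian
linear model on all other covariates plus stage and therapy indicators;
posterior-drawn coefficients; donor pool k = 5, so imputed values always
lie in the observed support), binary variables by logistic probability
draws; a degenerate inner fit falls back to marginal sampling with a
logged warning. Defaults: M = 20 completed data sets (M = 100 available by
configuration; both counts are in circulation for the reference analysis),
10 sweeps, variables imputed in order of increasing missingness.
Follow-up visits are never touched by imputation — LOCF at estimation time
is the only outcome imputation — and `locf_check` guards that contract.

## Pooling and contrasts

Per-imputation estimates q_m with within-variances u_m pool to
q̄ = mean(q_m), W = mean(u_m), B = var(q_m) (sample variance), total
T = W + (1 + 1/M)·B. Pooling is on the probability scale so structurally
empty cells stay exactly 0 with a zero-width interval (impossible on the
logit scale). 95% intervals default to the normal quantile, truncated to
[0, 1]; Rubin's t reference with large-sample degrees of freedom
(m−1)(1 + 1/r)², r = (1+1/m)B/W, is available by option. Contrasts pool
the per-imputation elementwise differences by the same rules (within
variances added), so the contrast point estimate equals the difference of
pooled points exactly; intervals truncate to [−1, 1]. Contrasting a
therapy's estimates with themselves short-circuits to the zero matrix with
zero-width intervals.

## Synthetic cohort generator

The generator stands in for the undeposited registry and defines the
study conditions for all simulation tests:

* **Covariates.** Marginals calibrated to the published cohort: log-normal
  age (median 38.6 y), PASI (median ≈ 9, σ_log = 1.155), BSA (median ≈ 14),
  duration (median ≈ 6 y); normal BMI (24.1) and DLQI (8, integer-rounded);
  eleven binaries at published proportions. A *mild* shared latent
  severity factor (loadings 0.2–0.5) correlates PASI, BSA, DLQI, duration,
  lesion sites and the baseline stage — enough joint structure for
  missing-at-random masking to bias complete-case means (which the
  imputation has to repair), while keeping the covariance near-diagonal.
  The baseline stage distribution (0.15, 0.30, 0.35, 0.20) is a realistic
  moderate-to-severe registry mix; it is not reported for the reference
  cohort.
* **Assignment.** Multinomial logit on standardized log-PASI, DLQI,
  log-duration and the centred stage, with severity-increasing
  coefficients for the biologic arm sized so the per-arm PASI/DLQI/
  duration medians reproduce the published pre-matching imbalance.
  Intercepts are calibrated at generation time (deterministic fixed-point)
  so marginal arm shares hit 53.7 / 13.7 / 32.6%.
* **Outcomes.** Each therapy × window has a latent 4×4 row-stochastic
  kernel (defaults: the published per-therapy matrices, row-renormalized
  since printed rows can sum to 0.99/1.01). Every visit's stage is an
  i.i.d. draw from the patient's kernel row, log-linearly tilted toward
  worse destinations for patients with above-average standardized log-PASI
  (`outcome_tilt`, default 0.25). The tilt creates residual confounding
  beyond the baseline stage — without it, the row-stratified naive
  estimator would already be unbiased and matching would have nothing to
  correct. With tilt 0, outcomes depend on (therapy, stage) only.
* **Visits.** 1 + Poisson(0.35) visits per patient per window at uniform
  integer days; the last visit realizes the window outcome; stage 0 maps
  to a random raw IGA of 0 or 1.
* **Missingness.** Masking probabilities are proportional to
  exp(slope × centred stage) — the stage is observed for everyone and
  never masked, so the mechanism is MAR by construction — and are rescaled
  by bisection so the marginal rate is exact even when probabilities
  saturate. Covariate slopes 0.8 (rates 1.5–8.1% by variable); per-window
  visit deletion at 62.1% / 48.8% with slope 0.15, i.e. severe stages are
  unobserved in ~77% vs ~50% for mild — differential but not saturated.
* **Determinism.** One `numpy.random.Generator` per operation, seeded from
  `TruthParameters.seed`; identical parameters give byte-identical CSVs.

What the generator does **not** emulate: treatment switching and
discontinuation, adverse events, visit-timing dependence on disease
course, any joint covariate structure beyond the single latent factor, and
informative (MNAR) missingness. Passing tests therefore demonstrate
internal validity of the estimation machinery under MAR and known kernels,
not robustness to those real-data features.

## Numerical choices

* Row sums of estimated/pooled matrices are asserted to 1e-9; kernel rows
  must sum to 1 within 1e-12 at validation.
* Singular metric covariance → ridge εI with ε = 1e-6·tr(S)/p, logged.
* Nearest-neighbor search runs in the whitened space (Cholesky of S⁻¹)
  with chunked exact distance computation; candidate pools are sorted by
  patient id so `argmin` realizes the lowest-id tie rule.
* The PMM linear solver adds 1e-8·tr(XᵀX)/p to the normal equations.
* Result CSVs round to two decimals, mirroring the published tables; the
  JSON twins keep full precision.

## Test and experiment scales

Simulation tests run at n = 150–20 000 depending on what they measure;
the end-to-end recovery experiment uses n = 4000, M = 10, 5 MICE sweeps,
three replicate seeds, with covariate missingness at default rates and
visit deletion disabled — kernel recovery is only defined without LOCF
deletion, which provably drags matrices toward the identity. At these
sizes the binding uncertainty is the systemic arm (13.7% of patients):
a baseline-stage row of that arm holds roughly 80–190 distinct donors,
and with-replacement weights shrink the effective sample further, putting
a ≈0.05 sampling floor under mid-range cells of its matrix. Max-cell
recovery bounds tighter than that floor are unattainable at this scale
regardless of implementation; the matched estimator nonetheless has
smaller absolute error than the naive per-arm estimator on the large
majority of confounded cells, and the recovery experiment is reported as
measured by `scripts/acceptance.py`.

## Known limitations

* LOCF is a strong assumption; matrices under heavy follow-up missingness
  are mixtures of true transitions and frozen baselines.
* The binomial cell variance ignores the matched design's weight
  clustering and is likely anticonservative; it is confined to one
  function for replacement.
* Normal-quantile CIs; the reference analysis's exact interval
  construction is not public, so interval widths are approximate
  reproductions while point estimates are exact arithmetic.
* Whether "overall" should pool the matched populations or the raw cohort
  is ambiguous in the reference analysis; the matched pooled population is
  implemented, and the naive path (`matched=None`) provides the
  alternative.
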