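# Methods

This note documents the statistical machinery in `chu9dmap`: the mapping
model, the four estimators, the selection/validation procedures, the
synthetic-data generator and the numerical choices behind each.

## The mapping problem

A mapping (crosswalk) algorithm predicts a preference-based utility — here
the CHU9D, anchored at full health = 1 with tariff floor 0.33 — from a
non-preference instrument, here the KIDSCREEN-10 (10 ordinal items, levels
1–5, coded so higher = better health; summarised by a Rasch-based T-score
index with mean ≈ 50, SD ≈ 10). Two functional forms are supported:

* **index form**: utility regressed on the index and its square (the
  quadratic captures the concave index–utility relationship; the
  fractional-logit variant omits the square because its link already
  bends the mean);
* **item form**: utility regressed on a selected subset of item raw
  scores. This is the flagship form — it needs no Rasch lookup table and
  every published item coefficient is positive, so better health on any
  item raises predicted utility.

Observed utilities are bounded above at 1 with a sizeable ceiling mass,
and left-skewed. Identity-link predictions can therefore exceed 1; the
package reports both the raw prediction and `min(ŷ, 1)`. Truncation is a
pointwise contraction toward any observation ≤ 1
(`|min(ŷ,1) − y| ≤ |ŷ − y|`), so it can only improve MAE and RMSE — this
is asserted as a theorem-style test, not an empirical observation.
Predictions are recommended for group-level use only; individual errors
are large (cross-validated MAE ≈ 0.09 on utilities spanning 0.33–1).

### The published registry

`chu9dmap/data/published_algorithms.json` transcribes all 16 published
coefficient sets (OLS / CLAD / MM / fractional logit × index/item form ×
Australian adolescent and UK adult tariffs), stored as decimal strings to
avoid binary-float transcription drift. Two source-table ambiguities are
flagged in the registry rather than silently resolved:

* the UK item-form table's flattened layout does not identify whether the
  small `ks_i10` coefficient 0.012365 belongs to the CLAD or the MM
  column; it is assigned to MM (mirroring the Australian table, where MM
  retains `ks_i10` with a similarly small coefficient) and the entry
  carries a `provenance_note`;
* evaluating the Australian CLAD item-form coefficients at all-fives
  gives 1.0897, while the source reports a maximum of 1.0802; the
  registry stores the coefficients as printed and no test pins CLAD
  extrema.

## Estimators

All four report heteroskedasticity-robust standard errors and
normal-approximation Wald p-values. The robust-SE flavour per estimator
(HC1 for OLS, pairs bootstrap for LAD/CLAD, asymptotic sandwich for MM,
GLM sandwich for the fractional logit) follows common practice for each
method and is recorded in `FitResult.se_method`.

**OLS.** Closed form via least squares; HC1 sandwich
`(n/(n−p)) (X'X)⁻¹ X'diag(e²)X (X'X)⁻¹`; R² reported.

**LAD.** `min Σ|y − Xb|` solved exactly as a linear programme with split
residuals (variables `b, u⁺, u⁻ ≥ 0`, equality `Xb + u⁺ − u⁻ = y`), HiGHS
solver with deterministic settings. The intercept-only model short-cuts to
the lower median (the LP optimum is any median on even n; the lower
median is the declared tie rule). SEs by seeded pairs bootstrap (default
B = 200; `n_boot=0` skips inference in Monte-Carlo loops).

**CLAD (Powell).** For ceiling-censored responses `y = min(y*, c)` (here
c = 1): iterate — fit LAD on the retained subsample, recompute fitted
values on the full sample, retain observations with fitted value ≤ c —
until the retained set repeats (boundary ties are retained; only fitted
values strictly above the censor point are excluded). Convergence is
declared on retained-set stability, max 100 iterations (non-convergence
is flagged, not raised); when censoring never binds the first retained
set is already stable and the estimate equals plain LAD exactly. SEs by
seeded pairs bootstrap of the whole procedure.

**MM.** Stage 1 is a 50%-breakdown S-estimator with the Tukey bisquare
(ρ standardised to max 1, consistency constant c₀ = 1.5476 solving
E[ρ(Z/c₀)] = 0.5): fast-S with 500 seeded p-subsets by default, 2 IRWLS
refinement steps per candidate, the best 5 by M-scale refined fully
(tolerance 1e-9, up to 50 steps). The M-scale solves
`mean ρ(r/s) = 0.5` by the standard multiplicative iteration. Stage 2 is
an IRWLS M-step at the scale fixed from stage 1, with the bisquare tuning
constant solved numerically from the requested Gaussian efficiency
(`(Eψ')²/Eψ² = eff`; 0.95 → c = 4.685), tolerance 1e-8, max 200
iterations. SEs from the robust sandwich
`s² (Σψ'ᵢxᵢxᵢ')⁻¹ (Σψᵢ²xᵢxᵢ') (Σψ'ᵢxᵢxᵢ')⁻¹`. Monte-Carlo studies in the
tests and acceptance script pass `n_subsets=50`: with p = 11 and at most
20% contamination, the probability that 50 random p-subsets contain no
clean subset is below 1e-4, and the reduced count keeps a 200-replicate
study under a couple of minutes.

**Fractional logit.** Quasi-binomial IRLS with logit link applied to the
utility on its observed scale — deliberately *without* rescaling the 0.33
floor to 0: this choice reproduces the published fractional-logit maxima
exactly (e.g. inverse-logit of the all-fives linear predictor 2.909110 =
0.9483) and keeps the canonical-link identity meaningful. With an
intercept, the score equation forces mean(inverse-logit fitted) =
mean(y) at convergence; the tests assert this to 1e-8. Sandwich SEs, as
the binomial variance is only a working assumption.

## Selection and validation

* **Forward stepwise**: greedy entry on robust-Wald p-values, threshold
  0.05; at each step the smallest p-value enters; exact ties break to the
  earliest-listed candidate; candidates collinear with the current model
  are skipped. Stepwise runs independently per estimator, which is what
  produces estimator-specific item subsets.
* **Bootstrap stepwise**: B seeded pairs-bootstrap resamples, stepwise on
  each, per-term selection counts; fit failures are counted, not fatal.
* **VIF**: `1/(1−R²ⱼ)` per non-intercept term; perfect collinearity is
  reported as `inf`.
* **Validation I (5-fold CV)**: seeded uniform shuffle, block split into
  five groups (sizes within one; exactly 118×5 at n = 590); each fold is
  predicted by a model re-estimated on the other four; the n held-out
  errors are pooled before computing MAE/RMSE.
* **Validation II (subsamples)**: the full-sample algorithm applied to
  seeded subsamples (without replacement) of sizes 100/300/500.
* MAE is the headline ranking criterion; RMSE ranks are reported
  alongside (`rank_report`).

The stepwise entry p-values use the same robust SEs as the final
inference; fold and subsample seeds are mandatory arguments, since the
original analysis's seeds are unknown.

## Synthetic data generator

The generator stands in for the unavailable 590-respondent estimation
sample. Mechanism: latent item propensities are one-factor Gaussian
(`R = λλ'` off-diagonal, unit diagonal), discretised to levels 1–5 by
fixed thresholds giving left-skewed marginals (3/7/15/35/40% — a healthy
community sample); latent utility is linear in the item scores plus
Gaussian noise, right-censored at 1 and floored at 0.33; the index is an
affine transform of the raw item sum.

The frozen defaults come from a one-off calibration (10⁶ draws, seeded):
item coefficients solve the censored item–utility correlation targets
(iterating to absorb censoring attenuation), and the affine utility scale
matches mean 0.808 / SD 0.155 after censoring. Under these moments the
implied ceiling mass is 0.146, which is stored as the config default and
verified within Monte-Carlo error; the floor mass is ≈ 0.5%. Loadings are
`1.1·r⁰·⁷⁵` per item: this is the structure that reproduces the published
correlation ordering (strongest "fit and well" 0.488 … weakest "free
time" 0.175) with **all true coefficients non-negative**, so that
selection-frequency rankings behave like the published ones. A
`calibrate()` function re-derives all constants for custom targets.

What the generator does *not* emulate: the study's multicollinearity
level (mean VIF ≈ 1.2 here vs 1.88 reported — pushing the latent
correlation high enough to match VIF forces a negative coefficient on the
weakest item and inverts the selection ranking); the exact selection
frequencies of the middle-ranked items (suppressor effects in the
one-factor structure make some weakly-correlated items enter more often
than in the real data); and any Rasch measurement process (the index is
an affine sum calibration, sufficient because the index form only uses
first and second moments of a monotone index). Passing tests therefore
show the pipeline's correctness and the estimators' statistical
properties under a realistic censored structure — not that the real
dataset's coefficient values are recovered.

Two auxiliary modes exist for targeted studies: `utility_model="logit"`
draws the response from a Beta distribution whose mean is
inverse-logit-linear in the items (the exact mean structure the
fractional logit assumes; its marginal mean sits slightly below 0.808 by
Jensen's inequality), and `contamination_rate` replaces a seeded fraction
of responses (in both the observed and the uncensored latent series) with
a gross outlier value (default −5) for robustness studies.

### Recovery harness

`recovery_harness` repeats generate → fit → compare-to-truth and reports
per-coefficient bias, Monte-Carlo SE of the mean estimate, empirical SE,
and coverage of the truth by ±2 robust SEs. Each estimator is evaluated
under its own model assumptions: OLS/MM on the uncensored latent response
(their estimand), CLAD on the censored observed response (its estimand is
the latent model under ceiling censoring), the fractional logit on the
logit-mean variant. Failure rates above 20% raise.

A note on reading the recovery z-scores: the "max |bias|/MC-SE over 11
coefficients" statistic is the maximum of correlated z-scores, so even an
exactly unbiased estimator exceeds 2 for a noticeable fraction of seeds;
the test suite evaluates it at a fixed seed, and the acceptance script
reports the value for whatever seed it is given.

## Problem sizes and determinism

Monte-Carlo studies use n = 590 (the study scale) with 200 replicates;
moment checks use n = 5000; oracle equivalences use n ≤ 15 where exact
enumeration is feasible. Every stochastic routine takes an explicit seed
(NumPy `default_rng`); derived seeds are drawn below 2³¹. LP solves,
IRWLS iterations and fold plans are deterministic given data and seed;
record-order permutation changes coefficients only within solver
tolerance (1e-8), except at exact LAD/stepwise ties, where the documented
lower-median / earliest-candidate rules apply.

## Known limitations

* The official Rasch lookup for the KIDSCREEN-10 index is manual-bound
  and not bundled; index-form algorithms need a user-supplied table (or
  work directly from index values), while the flagship item-form
  algorithms need none.
* CLAD inference is bootstrap-only; no analytic Powell covariance is
  implemented.
* No reverse mapping (CHU9D → KIDSCREEN-10), no prediction intervals, no
  imputation (complete-case only), and no external-dataset validation —
  validation is internal by design.
* Dataset-dependent published statistics (full-sample MAE/RMSE, means,
  VIFs, R²) are not reproduction targets: they depend on the undeposited
  sample. The package reproduces the data-free quantities exactly and the
  data-dependent ones in distributional character only.
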