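# Methods

## Linear epigenetic clocks

A clock is a linear predictor `age = b0 + Σ_j b_j β_j` over beta-values
β ∈ [0, 1] at a fixed CpG set, with `b0` in years and `b_j` in years per
unit beta. The shipped 3-CpG model (intercept 111.83; cg02228185 −64.57,
cg25809905 −42.57, cg17861230 +75.15) is carried as a packaged coefficient
file; any clock in the same two-column format (term, coefficient; one
`(Intercept)` row) can be loaded. Predictions are deliberately not clamped
to plausible ages: clamping would break the linearity identities the test
suite relies on (mixture linearity, and the exact propagation of a
constant beta shift `c` into a prediction shift `c·Σ_j b_j`, the mechanism
behind cross-platform offsets).

Retraining fits `age ~ β` by ordinary least squares on a specified CpG set
(explicit rank check; a rank-deficient design is an error that points to
the elastic-net option, which delegates the penalized fit to
scikit-learn). Leave-one-out cross-validation is used for error reporting
only — each sample is predicted by a model refit without it, by an actual
refit loop rather than a hat-matrix shortcut, so the independence of the
held-out prediction from that sample's age label holds by construction —
while the returned coefficients come from the full-data fit, the standard
practice for deployment. Whether a published small clock came from OLS or
a penalized fit is generally not determinable; both are offered and OLS is
the default. Single-CpG clocks are the univariate special case and refuse
zero-variance probes.

Evaluation reports Pearson r between predicted and chronological age, the
median of |delta_age| ("median error"), and the mean/SD of delta_age. A
pure offset inflates median error without reducing r — the signature of a
clock moved to a platform it was not trained on.

## Survival analysis

`delta_age / 5` enters a Cox proportional-hazards model with chronological
age and sex (male = 1; the delta_age hazard ratio is invariant to this
coding, which is asserted in tests), so the reported HR reads "per 5 years
of age acceleration". Deaths within the first `exclude_years = 2` of
follow-up are excluded before fitting — censored records are kept whatever
their time — to limit reverse causation from terminal illness. Removing
early deaths deletes no one from later risk sets, so the remaining partial
likelihood is still a valid one.

The Cox fit maximizes the partial likelihood by Newton–Raphson with
step-halving, on covariates standardized internally for conditioning
(estimates are transformed back). Efron's tie correction is the default —
matching the convention of the R `survival` package — with Breslow as an
option; the two coincide exactly when no event times are tied, which is
asserted. Risk-set sums are computed by suffix cumulative sums over
time-sorted samples, making each iteration O(n·p²). Convergence requires a
vanishing gradient (tol 1e-9) or a vanishing accepted step (1e-10; the
gradient has a numerical noise floor proportional to the summed risk
weights). Non-convergence within 100 iterations reports the last gradient
norm; a monotone likelihood (perfect separation) is detected either by a
diverging standardized coefficient during iteration or by an exploded
coefficient/SE at the plateau, and is an error rather than a silently
absurd estimate. Standard errors come from the observed information;
p-values are Wald tests; 95% CIs are `exp(coef ± 1.96·se)` with the
conventional literal 1.96 multiplier. Constant covariates are dropped with
a warning. The likelihood-ratio statistic against the null model is
exposed for cross-checks.

Kaplan–Meier curves are unadjusted product-limit estimates per stratum;
subjects censored at a death time count as at risk for those deaths. With
no censoring the estimate equals the empirical survival function exactly.
Covariate "adjustment" of a quartile comparison is interpreted as the
accompanying Cox model being adjusted — classical K-M admits no covariate
adjustment. The log-rank test is implemented for K groups (χ² with K−1
df) via the observed-minus-expected vector and its covariance; quartile
stratification is rank-based with stable tie-breaking by input order, so
group sizes differ by at most one and the assignment is deterministic.

The per-CpG screen trains a single-CpG clock per probe on the reference
cohort, predicts on the test cohort, and fits the adjusted Cox model on
`delta_age / 5` (option: raw beta instead, which gives similar results
when all participants are of similar age). Benjamini–Hochberg q-values
are computed within the screened family — one family per declared CpG set;
"significant" in reports means q < 0.05 within that family. Probes whose
fit is impossible (zero variance) are reported as NA with a warning and
excluded from the family size. NaN p-values propagate as NaN q-values.
Spearman correlation (average ranks for ties) is provided for relating
methylation to clinical covariates such as blood pressure.

## The synthetic cohort generator

The generator reifies the study design as a generative model — the
original analyses are observational and specify no mechanism, so the
proportional-hazards link between acceleration and mortality here is a
modelling choice, not a claim about biology.

* **Methylation.** Age CpG j: `β_ij = a_j + b_j (age_i + accel_i) + ε_ij`,
  clipped to [0, 1]; null CpGs have `b_j = 0`. Slope magnitudes are drawn
  uniformly from `slope_range` (default 0.002–0.005 beta-units/year) with
  random sign: a signed interval straddling zero would make many "age
  CpGs" nearly flat, contradicting the |r| > 0.85 selection rule that
  defines such probes, which the defaults reproduce (≥90% of age CpGs at
  noise_sd = 0.02 over ages 20–90). Intercepts are placed so noiseless
  trajectories stay within [0.05, 0.95] across the age range ± 3
  acceleration SDs, keeping boundary clipping rare; clipping after noise
  mildly attenuates slopes near the boundaries, which is documented
  β-value behaviour rather than a bug. The acceleration `accel_i ~
  N(0, 5²)` years is a single per-sample scalar shared by all age CpGs —
  the "biological age" reading; per-probe accelerations are out of scope.
* **Survival.** `h_i(t) = h0(t) · exp(θ·accel_i/5 + 0.4·male_i)` with
  exponential baseline `h0 = 0.08/yr` by default (Gompertz optional; any
  PH-consistent baseline is valid for a semi-parametric analysis, and the
  exponential is simplest to invert), administrative censoring at 15
  years, and a 10% fraction with uniform dropout censoring. Defaults give
  roughly three-quarters observed deaths over follow-up, the regime of an
  elderly mortality cohort. The default θ = log(1.11) mirrors the headline
  effect size the pipeline is designed to detect. Sex is exactly balanced
  so adjusted fits are well-conditioned.
* **Streams.** Random draws are split per component (probe truth, ages,
  noise, acceleration, sex, survival, censoring) via spawned seed
  sequences: changing survival parameters cannot reshuffle methylation
  draws, and identical configs give byte-identical cohorts after
  serialization. Train/test pairs share per-probe truth (drawn from the
  training config) with independent samples; the test config may add a
  constant platform offset.

What the generator does *not* emulate: cell-type composition shifts,
nonlinear pediatric trajectories, probe-specific noise heterogeneity,
batch structure, and age-dependent baseline hazard by default. Passing
tests therefore demonstrate correctness of the estimators and pipeline
under the stated generative model, not robustness to those real-data
complications.

## Verification strategy and problem sizes

Every estimator has a dual-route check: hand-worked small fixtures
(product-limit arithmetic, a six-subject log-rank worked through
observed-vs-expected bookkeeping, BH step-up by hand, tied-rank Spearman)
and an independent reference implementation (lifelines, statsmodels,
scipy) on randomized data; the Cox solver is additionally checked against
brute-force grid maximization of the written-out partial likelihood on
small no-ties fixtures.

End-to-end hazard-ratio recovery uses 50 replicates per true HR ∈ {1.0,
1.11, 1.5}: training cohorts of 500 samples × 10 age CpGs with noise_sd =
0.005 and no acceleration, test cohorts of 2,000 samples with
acceleration SD 5. The near-noiseless, acceleration-free training cohort
acts as the "perfect clock" condition: training on a cohort that itself
contains biological acceleration would shrink the fitted slopes
(regression attenuation) and bias the downstream log-HR upward by the
inverse shrinkage, a property of the design rather than of the estimator
(exactly noiseless betas are unusable for multi-CpG training — all
columns become affinely dependent on age and the design is rank-2). With
these sizes the measurement-error attenuation of the log-HR is below 1%.
Screen error control uses 100 replicates of 100-CpG all-null screens
(n = 500) and a planted 5-of-100 screen at n = 2,000; auxiliary property
tests (e.g. null log-rank behaviour) use smaller replicate counts chosen
to keep the default suite fast while leaving the assertions well above
their thresholds.

## Known limitations

* The Cox implementation covers right censoring with Efron/Breslow ties
  only: no time-varying covariates, stratified baselines, frailty,
  competing risks, or robust variances.
* BH assumes the usual independence/PRDS conditions; screens of highly
  correlated single-CpG predictors satisfy this empirically in tests but
  no theoretical guarantee is claimed.
* Clock training assumes complete beta matrices; imputation exists only
  at prediction time (fail-by-default, optional cohort-mean).
* The detection-rate filter is applied per cohort as loaded; pooling
  across waves before filtering is the caller's responsibility.
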