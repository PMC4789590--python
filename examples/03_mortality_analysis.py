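"""Age acceleration vs all-cause mortality on a synthetic cohort.

A cohort is simulated in which the true hazard rises 11% per 5 years of
epigenetic age acceleration (hazard ratio 1.11). The pipeline retrains a
clock on a reference cohort, predicts age on the test cohort, and tests
delta_age against survival: Cox regression per 5 years of delta_age
(adjusted for age and sex, deaths in the first 2 years excluded) plus a
log-rank comparison of the lowest vs highest delta_age quartiles.
"""

import math

from methclock import SimulationConfig, make_cohort_pair, run_clock_mortality

cfg_train = SimulationConfig(
    n_samples=500, n_age_cpgs=10, n_null_cpgs=0, noise_sd=0.005,
    acceleration_sd=0.0, seed=11,
)
cfg_test = cfg_train.replace(
    n_samples=2000, acceleration_sd=5.0, log_hr_per_5yr=math.log(1.11), seed=12
)
train, test = make_cohort_pair(cfg_train, cfg_test)
report = run_clock_mortality(train, test, clock=("retrain", None), seed=12)

ev = report["evaluation"]["test"]
print(f"clock on test cohort: r = {ev['pearson_r']:.3f}, "
      f"median error = {ev['median_abs_error']:.2f} years")
row = next(r for r in report["cox"]["summary"] if r["covariate"] == "delta_scaled")
print(f"delta_age HR per 5 years: {row['hr']:.3f} "
      f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}], p = {row['p']:.2g} "
      f"(true HR 1.11; {report['cox']['n_events']} deaths, "
      f"{report['cox']['n_excluded_early_deaths']} early deaths excluded)")
lr = report["logrank_q1_vs_q4"]
print(f"log-rank Q1 vs Q4: chi2 = {lr['chi2']:.2f}, p = {lr['p']:.2g}")
print()
print("the adjusted Cox CI excludes 1 and covers the true HR of 1.11. The")
print("unadjusted quartile log-rank is a blunter instrument: with an effect")
print("this small it is often non-significant in a single cohort draw.")
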