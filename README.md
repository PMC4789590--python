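# methclock

Linear DNA-methylation age clocks, age acceleration, and its association
with all-cause mortality.

## The problem

DNA methylation at certain CpG sites changes almost linearly with age, and
linear combinations of their beta-values ("epigenetic clocks") predict
chronological age from blood samples. The deviation of the epigenetic
prediction from calendar age,

```
delta_age = predicted_age − chronological_age,
```

partly reflects *biological* rather than chronological aging: in
longitudinal cohorts of older people, individuals with accelerated
epigenetic age (positive delta_age) die sooner. `methclock` is a tested,
reusable pipeline for this analysis aimed at epigenomics and biostatistics
researchers: it builds linear age predictors from beta-value matrices
(CpG × sample, values in [0, 1]), computes delta_age, and quantifies its
mortality association with Cox proportional-hazards regression
(hazard ratio per 5 years of delta_age, adjusted for age and sex, deaths
within the first 2 years of follow-up excluded), Kaplan–Meier curves of
the extreme delta_age quartiles with a log-rank test, and a per-CpG
survival screen with Benjamini–Hochberg FDR control.

The package ships the published Illumina-450K-retrained 3-CpG predictor

```
predicted age (years) = 111.83 − 64.57 β(cg02228185)   # ASPA
                               − 42.57 β(cg25809905)   # ITGA2B
                               + 75.15 β(cg17861230)   # PDE4C
```

and loads any clock from a two-column coefficient file in the same format
(e.g. 99-CpG, Hannum-71 or Horvath-353 tables). Because real mortality
cohorts are controlled-access, a first-class synthetic-cohort generator
produces beta matrices with linearly age-associated CpGs, measurement
noise, optional platform offsets, and survival times whose hazard scales
with the true age acceleration — so every stage is testable against known
ground truth.

The survival estimators (Cox partial likelihood with Efron/Breslow tie
handling by Newton–Raphson, Kaplan–Meier, log-rank, BH adjustment,
Spearman correlation) are implemented from first principles and verified
in the test suite against hand-worked fixtures and independent
implementations (lifelines, statsmodels, scipy).

## Worked example

`examples/03_mortality_analysis.py` simulates a reference cohort and a
2,000-sample test cohort whose true hazard rises 11% per 5 years of age
acceleration (HR 1.11), retrains a 10-CpG clock, and runs the full
survival analysis:

```
clock on test cohort: r = 0.971, median error = 3.48 years
delta_age HR per 5 years: 1.068 [1.009, 1.131], p = 0.023 (true HR 1.11; 1133 deaths, 355 early deaths excluded)
log-rank Q1 vs Q4: chi2 = 1.73, p = 0.19
```

The clock tracks chronological age closely (Pearson r = 0.97); the
adjusted Cox interval excludes 1 and covers the true hazard ratio of
1.11; the unadjusted quartile log-rank is a blunter test and, for an
effect this small, often non-significant in a single draw. The other
examples demonstrate the 3-CpG model arithmetic
(`01_three_cpg_clock.py`), platform-offset propagation through a trained
clock (`02_simulate_and_train.py`), and the per-CpG screen recovering 5
planted mortality CpGs among 45 age-associated decoys at q < 0.05
(`04_cpg_screen.py`).

A thin CLI mirrors the library stages
(`methclock simulate | train | predict | survival | screen | report`),
reading and writing the package's delimited-text formats.

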