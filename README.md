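# ordval — ordinal clinical prediction models with honest validation

`ordval` builds and compares prediction models for **ordinal clinical
outcomes** — here, the three-level dehydration severity (*none < some <
severe*) of patients presenting with acute diarrhea — and measures how much
of a model's apparent performance survives honest validation. It is aimed at
biostatisticians and clinical-ML researchers who want a worked, fully
reproducible pipeline for:

* **Four model families** behind one probability contract:
  proportional-odds logistic regression with forward stepwise selection of
  main effects and pairwise interactions (POLR), ridge-penalized parallel
  cumulative-logit regression (RIDGE), ordinal classification trees with
  absolute rank-distance costs (CART), and bagged ordinal forests with
  per-split variable sampling (RF).
* **Three ordinal concordance indices.** For a scalar risk score S and
  outcome Y ∈ {1 < 2 < 3}, all generalize the binary c-statistic
  (0.5 = chance, 1 = perfect):
  - ADC — mean of the K−1 binary AUCs over the cumulative splits Y ≤ k vs Y > k;
  - ORC — unweighted mean of the K(K−1)/2 between-category AUCs;
  - GC — concordance over all cross-category pairs, equal to the
    n_i·n_j-weighted mean of the pairwise AUCs.
* **Tuning by 10-fold cross-validation** maximizing held-out log-likelihood
  over a candidate grid (model size for POLR, λ for RIDGE, (cp, minsplit)
  for CART, mtry for RF), refitting on all data at the selected value.
* **Bootstrap optimism correction** around the *full* modeling process
  (encoding, tuning, selection rerun per replicate): Harrell's method
  A − mean(A_b − O_b), Efron's 0.632 estimator 0.368·A + 0.632·mean(OOB_b),
  and the 0.632+ estimator with relative overfitting rate
  R = (A − mean(OOB_b))/(A − γ), γ = 0.5.
* **External validation** on a later, covariate-shifted cohort with frozen
  preprocessing (reference levels, bins, spline knots, retained columns).

Real cohorts are not bundled; a first-class synthetic generator draws
cohorts with the same structure (14 predictors per the clinical sign/bin
schema, cumulative-logit outcome with calibrated intercepts, a quadratic
age effect and a sign-by-sign interaction, and a shifted validation wave),
plus per-patient rehydration weight courses so the criterion-standard
outcome (percent weight change; severe > 9%, some 3–9%, none < 3%) is
testable end to end. User-supplied cohorts are accepted as CSV.

## Worked example

The analysis drivers run the whole study on synthetic cohorts:

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_criterion_standard.py --seed 1
python analysis/03_compare_models.py --seed 1
python analysis/04_bootstrap_diagnostics.py --seed 1
```

`01` prints realized vs target outcome marginals, e.g. for the derivation
cohort (n = 2139): none 20.8% (target 20.1), some 67.6% (66.9), severe
11.6% (12.9), and for the shifted validation wave (n = 1580): severe 7.8%
(7.6) with median age 28.2 vs 34.6 years — the intercept calibration and
covariate shift doing their jobs. `03` runs the reduced-scale comparison
(n = 200/150, B = 50 bootstrap replicates, coarse grids; ~2 min) and
prints the comparison grid, e.g. the ADC rows:

```
Index Model           Train         Harrell     Efron 0.632    Efron 0.632+            Test
  ADC  POLR 0.81(0.75,0.87) 0.78(0.74,0.82) 0.77(0.68,0.83) 0.76(0.64,0.83) 0.74(0.66,0.80)
  ADC    RF 1.00(1.00,1.00) 0.91(0.87,0.94) 0.82(0.75,0.89) 0.78(0.65,0.87) 0.72(0.66,0.81)
  ADC RIDGE 0.87(0.81,0.90) 0.81(0.76,0.87) 0.81(0.75,0.86) 0.81(0.73,0.86) 0.79(0.72,0.86)
  ADC  CART 0.59(0.55,0.63) 0.56(0.50,0.60) 0.58(0.53,0.63) 0.58(0.50,0.63) 0.53(0.50,0.56)

ADC train-to-test drop: RF +0.28 vs POLR +0.08
```

Read it as: the deep forest looks perfect on its own training data
(apparent ADC 1.00), the bootstrap corrections claw most of that back
(0.632+ gives 0.78), and the external test on the shifted wave takes it to
0.72 — while the 3-variable POLR model barely moves (0.81 → 0.74). `04`
prints the mechanism: size-2139 bootstrap resamples contain 36.79%
duplicate draws on average, which deep trees memorize; and the chance /
perfection anchors of all three indices (≈0.50 on outcome-independent
scores; exactly 1.0 under strict separation).

Everything the drivers do is importable from `ordval.*` (synthetic
cohorts, preprocessing/encoding, the four families, `tuning.tune_*`,
`metrics.ordinal_indices`, `validation.optimism_correct`,
`experiment.run_comparison`).

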