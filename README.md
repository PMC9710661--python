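# denvar

Threshold-free stratification of multiplex tissue-imaging cohorts by the
probability density of a functional marker.

## The problem

Multiplex imaging platforms (mIHC, MIBI, CODEX, ...) quantify continuous
marker intensities in every segmented cell of a subject's tumor
microenvironment. For functional markers such as HLA-DR, PD1, PD-L1 or Lag3,
the standard analysis binarizes each cell with a positivity cutoff `t1` and
then splits subjects by whether their positive-cell proportion exceeds a
second cutoff `t2`. Both cutoffs are subjective, and binarizing discards most
of the intensity information.

`denvar` instead treats each subject's marker expression as a continuous
random variable on [0, 1] (after pooled min-max scaling) and compares
subjects through their whole densities:

1. per subject *j*, a Gaussian KDE `f̂_j(x) = n_j⁻¹ Σ_i w_h(x − X_ij)` with
   Silverman's rule-of-thumb bandwidth `h = 0.9 min(sd, IQR/1.34) n^(−1/5)`,
   evaluated on a shared grid of R = 1024 equidistant points and normalized
   to unit mass;
2. the Jensen–Shannon divergence between every pair of subjects,
   `JSD(p, q) = Σ_r [p_r ln(2p_r/(p_r+q_r)) + q_r ln(2q_r/(p_r+q_r))]`,
   bounded by 2 ln 2, whose square root is a metric;
3. hierarchical clustering of the distance matrix into K groups, tested
   against outcomes (Wald test for continuous, Cox partial-likelihood ratio
   test for survival); or, skipping the clustering, the similarity matrix
   `G = exp(−JSD)` used directly as the covariance of a subject-level random
   effect — a variance-component LRT in a linear mixed model for continuous
   outcomes, and a correlated Gaussian frailty in a Cox model (Laplace
   approximation) for survival.

The two classical comparators — two-threshold positivity clustering and
K-means on extreme-quantile vectors — are implemented alongside, plus a
Monte-Carlo study harness that measures every method's adjusted Rand index
on simulated two-group cohorts.

## Worked example

```sh
denvar fixtures --outdir example
denvar distance --cells example/cells.csv --marker HLA-DR --cell-type CK+ \
    --out example/D.csv
denvar cluster --distance example/D.csv --k 2 --out example/labels.csv
denvar test --labels example/labels.csv --outcome example/outcome_survival.csv \
    --model coxph --out example/cox.json --km-plot example/km.png
```

prints

```
wrote 12x12 distance matrix to example/D.csv
wrote 2-group labels for 12 subjects to example/labels.csv
coxph-label-lrt: statistic=6.7097 p=0.009589
```

The bundled cohort has 12 subjects whose CK+ cells follow two distinct
intensity profiles; survival times are shorter in the second group. The JSD
matrix separates the profiles, the dendrogram cut recovers the two groups,
and the Cox likelihood-ratio test rejects equality of hazards (statistic
6.71 on the χ²(1) reference, p ≈ 0.0096, fitted hazard ratio ≈ 10 in this
small, well-separated toy cohort);
`example/cox.json` also records the fitted hazard ratio and `example/km.png`
shows the annotated Kaplan–Meier curves. Passing `--distance` instead of
`--labels` to `denvar test` runs the variance-component (or frailty) route
on `G = exp(−JSD)` without ever forming hard clusters.

The simulation study is available both as a library
(`denvar.simulation_study.run_study`) and a command:

```sh
denvar simulate --design beta-shift-A --n 200 --l 100 --reps 100 --seed 1 \
    --out reps.csv --summary summary.csv
```

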