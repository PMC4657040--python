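# relfdr

Reliability-aware local false discovery rate (lfdr) estimation for omics
feature tables measured in technical replicates, aimed at untargeted LC/MS
metabolomics.

## The problem

Untargeted LC/MS profiling with lenient peak detection yields thousands of
features, many of which are chemical or bioinformatics noise, and real
features are measured at very different levels of technical reliability.
Classical multiple-testing procedures (Benjamini–Hochberg, Storey
q-values, one-dimensional lfdr) treat all features identically, so
low-reliability and pure-noise features dilute the null distribution and
cost real statistical power.

`relfdr` quantifies each feature's technical reliability from its
replicates and compares each feature's association statistic only against
the null behavior of features with *similar* reliability — a soft
stratification implemented as a two-dimensional lfdr.

## The method

For feature *i* with log-intensity x_ijk (sample *j*, replicate *k*,
zeros marking "not detected"):

- **Replicate collapse.** x̄_ij = mean of the detected replicate values
  (0 only when all replicates are 0).
- **Repeat Reliability Index (RRI).** s_ij = SD of the detected
  replicates of cell (i, j) when at least two are detected, else NA;
  r_i = mean of the non-NA s_ij. Small r_i = reliable feature. Scores
  above the 99th percentile are compressed to that percentile.
- **Association scan (MWAS).** Per feature, OLS of x̄_i· on
  [intercept, risk factor, confounders]; t_i is the risk-factor t-statistic.
- **Permutation null.** The risk factor is permuted B = 10 times
  (confounders stay attached to their samples) and the scan re-run,
  pooling B·m null statistics; reliability scores are unchanged by the
  permutation.
- **Two-groups model.** f(z) = π₀ f₀(z) + (1 − π₀) f₁(z) and
  lfdr(z) = π₀ f₀(z) / f(z), with z = t (fdr1d) or z = (t, r) (fdr2d).
  Densities are binned Gaussian KDEs with direct plug-in (Sheather–Jones /
  Wand–Jones) bandwidths; π₀ comes from Efron's central-matching fit to
  the 1D statistics.
- **Independence null (the headline estimator).** Because technical
  reliability is independent of the test statistic under the null,
  f₀(t, r) = f₀,t(t) · f₀,r(r) — a product of two 1D densities that is far
  more stable than a direct 2D fit where points are sparse. The direct 2D
  fit (`fdr2d_full`) is available when the independence assumption is in
  doubt.

Features with lfdr < 0.2 (strict) are called significant by default.

## Worked example

```bash
relfdr simulate --preset paper --signal 1.5 --n-de 300 --seed 1 --out-prefix demo
relfdr lfdr demo_features.csv demo_covariates.csv \
    --risk-factor group --allow-negative \
    --method fdr2d-product --method fdr1d --seed 2 --out demo_lfdr.csv
```

which prints

```
wrote demo_lfdr.csv; pi0=0.942; significant at lfdr<0.2: {'fdr2d_product': 249, 'fdr1d': 218}
```

The simulated table has 8000 features (5000 structured metabolites with
block-correlated expression, 3000 pure-noise features) in 100 samples
measured in triplicate, 300 of them shifted by 1.5 in the disease group.
π₀ ≈ 0.94 is the estimated fraction of null features. The
reliability-aware estimator flags 249 features versus 218 for the
statistic-only 1D estimator — the extra discoveries are concentrated in
reliably measured, truly shifted features (compare against `demo_truth.csv`).
Every result CSV gets a `.meta.json` sidecar (seeds, π₀, bandwidths, grid
spec) sufficient to regenerate it.

The same machinery is available as a library:

```python
from relfdr import SimulationConfig, simulate_dataset, run_pipeline

data = simulate_dataset(SimulationConfig(n_de=300, signal=1.5, seed=1))
table, meta = run_pipeline(data.tensor, data.covariates, B=10, seed=2)
```

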