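# Methods

## Model

`relfdr` works in the empirical-Bayes two-groups framework. Each feature
carries a statistic z; the marginal density of z across features is

    f(z) = π₀ f₀(z) + (1 − π₀) f₁(z)

where f₀ is the density among null (not differentially expressed)
features, f₁ among non-null features, and π₀ the null proportion. The
local false discovery rate is the posterior null probability

    lfdr(z) = π₀ f₀(z) / f(z),

clipped to [0, 1] since the plug-in ratio can exceed 1 in the tails. f₁ is
never estimated directly; it exists only implicitly through f and f₀.

Three estimators share this skeleton and differ in z and in f₀:

| tag            | z        | f₀                                              |
|----------------|----------|-------------------------------------------------|
| `fdr1d`        | t        | 1D KDE of pooled permuted statistics (or the t density at the model's df with `null="theoretical"`) |
| `fdr2d_full`   | (t, r)   | direct 2D KDE of the pooled (t*, r) cloud        |
| `fdr2d_product`| (t, r)   | f₀,t(t) · f₀,r(r), product of the two 1D marginal KDEs |

r is the Repeat Reliability Index (below). The product form is justified
because technical reliability is independent of the test statistic under
the null; it is markedly more stable than the direct 2D fit in sparse
regions, which are exactly the regions that decide significance. When the
independence assumption is doubted, `fdr2d_full` is the fallback.

## Repeat Reliability Index

For log-intensities x_ijk with 0 encoding "not detected": a cell's
collapsed value is the mean of its detected (non-zero) replicates; its
within-sample SD s_ij (n−1 denominator) is defined only when ≥ 2
replicates are detected, otherwise NA ("the variation is unquantifiable").
r_i is the mean of the non-NA s_ij. Zero is perfectly reliable; there is
no upper bound, so scores above the 99th percentile are compressed to that
percentile before density estimation. The cap is an order statistic
(quantile `method="higher"`), which matches the intuition "the value
larger than 99% of the others" and makes the compression exactly
idempotent — a linear-interpolation quantile would drift by a few 1e-5 on
re-application.

Detection is defined as x ≠ 0, not x > 0: the synthetic generator centres
log-intensities at zero, so negative values are legitimate measurements.
File input is still validated non-negative by default (real log-intensity
tables are), with `allow_negative` for centred tables.

Features with r_i = NA (never detected twice in any sample) are assigned
the winsor cap — the least-reliable finite score — keeping them testable
with worst-case reliability; `na_policy="drop"` removes them instead.
Winsorization is computed on the finite scores before this substitution.

## Association scan and permutation null

Per feature, OLS of the collapsed intensity on [intercept, risk factor,
confounders] (categorical confounders expand to treatment contrasts). The
statistic is the risk-factor coefficient t. Collapsed zeros enter the
regression as-is; numerically constant responses yield t = 0 with a
warning rather than 0/0.

The null is built by permuting the risk factor alone — confounders stay
attached to their samples — B = 10 times, re-running the scan, and pooling
all B·m statistics into one sample ("pooling" rather than averaging B
densities: equivalent in expectation and simpler). Reliability scores are
untouched by permutation, so the null r-marginal is the observed r vector
tiled B times.

## Density estimation

Gaussian-kernel KDE with linear binning on an equally spaced grid
(default 401 nodes per axis, spanning the data range ± 3 bandwidths),
evaluated by linear/bilinear interpolation with edge clamping and a floor
of 1e-10 to keep ratios finite. 2D estimation uses a product kernel with
independent per-axis bandwidths and no cross term.

Bandwidths come from the two-stage direct plug-in rule (normal-scale start
for the 8th-order functional, two kernel-functional refinements, then the
AMISE-optimal h), computed on linear bins; the implementation agrees with
the reference R implementation of this rule to ~1e-5 relative on test
samples. Each density gets its bandwidth from the sample it is fitted to:
observed densities from the observed marginals, null densities from the
pooled permuted dataset (so the null r-axis bandwidth is the plug-in value
of the B-tiled reliability vector — a sample 10× larger, hence a smaller
bandwidth). This makes the full-2D null KDE noticeably noisier than the
product null, which is precisely the instability the product estimator is
designed to avoid; on null simulations ~97% of high-density features agree
between the two within 0.1 lfdr, with a small tail of larger differences
near the winsor atom.

## π₀ estimation

Efron's central-matching recipe on the 1D statistics: histogram (120
bins), Poisson regression of counts on a degree-7 polynomial to smooth the
log mixture density, a quadratic fit over the central 50% of mass to
identify an empirical-null Gaussian N(δ₀, σ₀²), and
π₀ = √(2π) σ₀ f̂(δ₀), capped at 1. Below 200 statistics the fit is
unreliable and π₀ = 1 is returned with a warning (the conservative
choice). The same π₀ is reused by both 2D estimators — low-reliability
features inflate the 1D estimate slightly, which makes the whole
procedure conservative (π₀ 0.8 → 0.9 inflates every lfdr by ×1.125).

A consequence of central matching is that π₀·f₀ ≈ f at the centre of the
null bulk, so a fraction of clearly-null central features sits at ratio
≥ 1 and clips to lfdr = 1 (roughly a quarter on the benchmark recipe).
This is standard behavior of this π₀ family and harmless: clipping only
touches features that would be called null regardless.

Significance is strict: lfdr < threshold (default 0.2).

## Synthetic data generator

The generator emulates a replicated untargeted LC/MS study on the log
scale and is the basis of all benchmarks. Defaults are the benchmark
study conditions:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| n_real           | 5000    | structured metabolites                         |
| n_noise          | 3000    | pure-noise features, N(0, max_noise_sd²)       |
| n_samples_per_group | 50   | control / disease                              |
| n_replicates     | 3       | technical triplicates                          |
| max_noise_sd     | 2.5     | per-feature noise SD ~ U(0, 2.5)               |
| signal           | 0       | additive shift in the disease group            |
| n_de             | 0       | differentially expressed metabolites           |
| zero_rate        | 1/30    | per-feature zero count ~ ⌊Exp(rate)⌋, mean 30  |
| sd_profile       | (1.3, 1.6, 1.9) | target SD quartiles of real features   |

Steps, in order: (1) multivariate-normal base expression; (2) each sample
column repeated 3×; (3) per-replicate Gaussian noise with per-feature SD
~ U(0, 2.5); (4) signal added to every disease-group entry of the n_de
chosen features; (5) pure-noise block appended; (6) zeros placed uniformly
at random (so zeroing can erase signal entries — faithful to how
missingness hits real tables).

The base covariance is a surrogate for a covariance extracted from real
data that cannot be distributed: per-feature SDs drawn from a normal
matched to the quartile profile (truncated at 0.1), random blocks of 2–20
features with compound-symmetric correlation ~ U(0.3, 0.9), sampled by a
one-factor representation without any dense factorisation. It preserves
the two properties that matter downstream — the SD profile and the
presence of correlated features — but not real-data features such as
heavy-tailed intensities, batch drift, m/z-dependent noise or structured
missingness. Passing benchmarks therefore demonstrate correctness of the
machinery under the stated generative model, not performance on any
particular instrument's output.

Baseline means are 0 (only variances are specified); this is irrelevant
to t-statistics and to the RRI, which depend on contrasts and replicate
scatter respectively.

The null benchmark simulates 5000 structured metabolites with no signal
and no pure-noise block — the configuration whose false-positive *rate*
denominator is 5000 — while power benchmarks use the full 8000-feature
recipe.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` use: 20 seeds for the p-value
demonstration (5400 p-values each); 10 null datasets of 5000 metabolites
× 100 samples × 3 replicates with B = 10 permutations; 3 datasets at
(signal 1.5, n_de 300) for the power-ordering check; m = 300 for the
exact-kernel-sum oracle; scaled-down (≈1200-feature) datasets for
structural pipeline tests. The full 5 × 4 × 10 scenario grid is available
via `relfdr benchmark --preset paper-grid`.

## Numerical choices and edge cases

- Quantile convention for the winsor cap: order statistic ("higher").
- Degenerate reliability (all features share one value): the second
  dimension cancels and both 2D estimators reduce to `fdr1d`.
- Degenerate design (collinear confounder): hard error naming the column;
  silent misalignment is worse than a failure.
- Sample order is the only alignment between the feature table and the
  covariate table; there is no join by ID.
- NaN intensities on input are treated as 0 (not detected) with a warning.
- Ties at the significance threshold are not significant (strict <).
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`/`SeedSequence`; identical seeds give bitwise
  identical datasets and results.

## Known limitations

- The RRI captures technical variation only and requires replicates
  (M ≥ 2 for any non-NA score); alternative reliability scores (peak-shape
  fit, missingness fraction) are out of scope.
- No moderated/shrunken t-statistics; the scan is plain OLS.
- No adaptive-bandwidth KDE and no boundary correction; the reliability
  axis is bounded below at 0 and the KDE smears a little mass below it.
- The average false-positive counts in the null benchmark are means of
  small counts over 10 datasets and vary noticeably between meta-seeds.
- With fewer than ~200 features π₀ falls back to 1 and lfdr values are
  conservative.
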