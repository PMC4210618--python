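# Methods

## Model and procedure

The package tests, feature by feature, whether the within-group spread of
a measurement differs between sample groups. Let Y be a G × N matrix of M
values (log2 methylated/unmethylated ratios; beta-scale input is mapped
through the base-2 logit first) and X an N × p full-rank design matrix.

1. **Mean fit.** Ordinary least squares is run independently per feature:
   β̂_g = (XᵀX)⁻¹XᵀY_g, residuals r_gj = Y_gj − (Xβ̂_g)_j.
2. **Leverage-corrected deviations.** z_gj = |r_gj| / (1 + h_j) with h_j
   the j-th diagonal of the hat matrix H = X(XᵀX)⁻¹Xᵀ (or r²_gj/(1+h_j)
   for the squared-deviation variant). For a group-means design
   h_j = 1/n_k, so the factor reduces to n_k/(n_k+1); the hat-matrix form
   extends the same correction to arbitrary covariate designs. Samples
   with h_j = 1 (singleton groups, saturated designs) are rejected: their
   residuals are identically zero and spread is not estimable.
3. **Moderated t on deviations.** The same design is fitted to z, giving
   deviation-mean contrasts β̂ᶻ_g, residual variances s_g² with
   d = N − p degrees of freedom. A scaled-inverse-chi-square prior
   (d₀, s₀²) is estimated from {s_g²} by moment matching on the log scale
   (below); posterior variances s̃_g² = (d₀s₀² + d·s_g²)/(d₀ + d) feed
   t̃_g = cᵀβ̂ᶻ_g / (s̃_g √(cᵀ(XᵀX)⁻¹c)) with d₀ + d total df (two-sided
   p-values; df capped at 10⁶, where t is numerically normal).
4. **FDR.** Benjamini–Hochberg step-up adjustment (via statsmodels).

The intuition is Levene's: a variance difference is a *location*
difference in absolute deviations, and a t-test on deviations inherits
the t-test's robustness — one aberrant sample moves one deviation, not a
squared ratio of variances. The companion mean test (`diff_methylation`)
is the same empirical-Bayes machinery applied to Y directly, reporting
the group difference of mean beta values (Δβ) as its effect size.

### Prior estimation

With e_g = log s_g² − ψ(d/2) + log(d/2) (an unbiased estimator of
log σ_g²), set m = mean(e) and v = sample variance of e (ddof 1). Solve
ψ′(d₀/2) = v − ψ′(d/2) for d₀ by Newton iteration on the monotone
trigamma function (relative tolerance 1e-8, ≤50 iterations, asymptotic
start 0.5 + 1/x, bisection fallback), then
s₀² = exp(m + ψ(d₀/2) − log(d₀/2)). If v ≤ ψ′(d/2) the ensemble shows no
excess dispersion and d₀ = ∞ with s₀² = exp(m) — note exp(m) carries the
chi-square log-bias correction, so even for identical s_g² ≡ c the prior
scale is c·(d/2)/exp(ψ(d/2)), slightly above c. Features with s_g² = 0
are excluded from moment matching (counted and logged) but still
squeezed and tested. A single-feature input cannot support prior
estimation; the pipeline then falls back to d₀ = 0 (no shrinkage — the
classical t), which `ModerationParams` represents explicitly.

The construction was cross-checked against limma's `fitFDist`/
`squeezeVar` (R) in the test suite; the two agree to 6+ significant
digits on a common fixture.

## Significance filters

Following common practice for cancer/normal 450k comparisons, a site is
called significantly differentially variable when its BH-adjusted p is
below 5% **and** its variability ratio — max/min of the two unbiased
group variances of the M values, direction recorded separately — is at
least 5. The mean test's filter is FDR < 5% and |Δβ| ≥ 0.1. Both
thresholds are parameters. The ratio is computed on the M scale, the
scale the test operates on.

## Baselines

The F test (two-sided: p = 2·min(P(F≤f), P(F≥f)) on (n₁−1, n₂−1) df) and
Bartlett's test (upper-tail χ²_{K−1}; the statistic is non-negative and
one-sided by construction, so a two-sided tail would be nonstandard) are
vectorised across features. Degenerate zero-variance groups yield p = 0
(logged) rather than errors, so genome-scale runs never crash on a
constant probe.

## Simulation engine

`simulate_dataset` draws, per feature: a true variance
σ² = d₀s₀²/χ²_{d₀} (defaults d₀ = 20, s₀² = 0.64 — d₀ = 20 puts weight
20/(20+50) ≈ 0.29 on the prior for 50-sample groups, and 0.64 is
slightly above hyperparameter estimates from large 450k cancer cohorts);
a mean of +2 (methylated) or −2 (unmethylated), exactly half each by
default, shared by both groups; then normal M values. Differentially
variable features draw group-1 and group-2 variances *independently*,
group 2 from an inflated prior scale (1.5 by default ⇒ mean variance
ratio 1.5/0.64 ≈ 2.34; 3.2 and 6.4 give five- and ten-fold ratios — the
fold convention is the ratio of prior scales, anchored by the 2.34
computation). Outlier-bearing features have one uniformly chosen sample
replaced by the global pre-injection maximum of the matrix; outlier
features are disjoint from DV features unless `allow_overlap=True`
(overlap status of the original protocol is unstated; disjoint is the
cleaner ground truth). All randomness flows from `SimConfig.seed`
through `SeedSequence` spawning, so any table cell is reproducible;
sweep replicates derive their streams from (base seed, size, rep).

What the generator emulates: the bimodal marginal distribution of array
M values, heavy-tailed feature-to-feature variance heterogeneity,
single-point contamination. What it does not: probe-type (Infinium I/II)
chemistry differences, spatial/batch effects, correlation between
neighbouring CpG sites, beta-scale heteroscedasticity (features are
generated directly on the M scale). Passing benchmarks therefore
demonstrate robustness and calibration under exchangeable-feature
conditions, not performance on raw array artefacts — `resample_split`
exists precisely to rerun the null benchmarks on a user's own
single-condition matrix, preserving inter-feature correlation.

## Evaluation conventions

Type-I error uses **raw** p-values at nominal cutoffs and reports the
median across replicates (mean and sd are included for diagnostics); FDR
and power use **BH-adjusted** p at a 5% cutoff, with FDR = 0 when
nothing is discovered and power undefined (NaN) when no DV features
exist. ROC curves rank by ascending p with stable tie-break on input
order; outlier-bearing null features count as negatives (they are not
truly differentially variable, so ranking them highly must cost false
positives). AUC is the trapezoid over the ranked points and equals the
normalized Mann–Whitney U on continuous p (tested).

## Benchmark scales

The test suite reruns the benchmark battery at desk scale, chosen so the
full default suite completes on a single CPU while keeping Monte-Carlo
error well inside the comparison tolerances: 200 replicates of
10,000 features × 50 + 50 samples for the type-I tables (reference
values from 1000-replicate runs; comparisons use 3 MC standard errors
with the per-level sd √(a(1−a)/G) scaled by √(1000/200)), 50 replicates
for the ROC comparison, and 50 replicates per size for the 10-size
sample-size sweep at 50,000 features. `scripts/acceptance.py` uses the
same 50-replicate, 50,000-feature configuration for its power figure.

## Known limitations

- Deviations are computed from the ordinary mean fit and then scaled;
  the leverage factor is exact for grouped designs and first-order for
  general covariates. For balanced two-group designs the factor is a
  common constant and cancels from the t entirely.
- Absolute deviations of normal data are half-normal, not normal, so the
  moderated t is slightly anticonservative at large G (observed ~0.052
  at nominal 0.05 under the simulation null); the squared-deviation
  variant is conservative at small cutoffs instead.
- No variance-vs-mean trend is modelled in the prior, and hyperparameter
  estimation is the plain moment-matching variant (no robust
  winsorisation).
- I/O rejects missing values by design: imputation would distort the
  variances under test. Filter probes upstream.
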