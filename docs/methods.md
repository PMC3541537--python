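# Methods

## Estimators

**Pearson / Spearman.** Product-moment r with T = r√((n−2)/(1−r²)) and a
two-sided Student-t p-value on n−2 df; Spearman is the same machinery on
midranks (ties share averaged ranks), using the t approximation for p.

**Percentage-bend correlation.** Per margin: M = median; ω̂ = W₍ₘ₎, the
m-th order statistic of the absolute deviations |v − M| with
m = ⌊(1−β)n⌋; with U = (v − M)/ω̂, the bent location is
θ̂ = (Σ_{|U|≤1} v + ω̂(i₂ − i₁))/(n − i₁ − i₂) where i₁, i₂ count
observations below −1 / above +1. The transformed scores are
A = Ψ((v − θ̂)/ω̂) with Ψ clipping at ±1, and r_pb is the product-moment
formula on (A, B), tested with the same t statistic. Two conventions for
m circulate (with and without a +0.5 rounding term); this implementation
uses ⌊(1−β)n⌋, which reproduces the published Anscombe values exactly
(pair 2: r = 0.8037, p = 0.0029; pair 3: r = 1) where the rounded index
does not. At β = 0 no observation is bent — Ψ is skipped, θ̂ is the mean,
and r_pb equals Pearson's r identically. A margin whose bend scale
collapses to zero (more than (1−β)n identical values, e.g. Anscombe
pair 4's x) is reported as a degeneracy error rather than a number.

**Skipped correlations.** (1) Robust center by MCD (below);
(2) every point j is projected onto the ray from the center through each
point i, keeping the *signed* scalar projection; (3) direction i flags
point j when its projection falls outside median ± g·(q₃ − q₁), with
ideal-fourths quartiles per direction and gate g = √χ²₀.₉₇₅(1) ≈ 2.2414
(a MAD-median variant replaces the IQR with MAD/0.6745); a point flagged
in any direction is removed; (4) Pearson/Spearman on the m survivors,
with h = 1 iff |T| > 6.947/n + 2.3197 at the *original* n. Signed
projections with a two-sided cutoff — rather than absolute distances
with a one-sided cutoff — are used because only they reproduce the
canonical Anscombe flag patterns (no flags in pairs 1–3, exactly
(19, 12.5) in pair 4) together with the published small-sample error
rates; an absolute-value variant flags the low corner of pair 2's
parabola under every robust center we tried. The decision is only
calibrated at α = 0.05; other levels should use the bootstrap CI.

## MCD center

The minimum covariance determinant estimator with coverage
h = max(⌊0.75 n⌋, ⌊(n+3)/2⌋). For n ≤ 12 every h-subset is enumerated,
so the result is exact and seed-independent; for larger n a
concentration-step search (50 elemental starts, C-steps to convergence
on the best 10) approximates the optimum and is deterministic per seed.
The raw subset covariance is scaled by the asymptotic consistency factor
α/P(χ²₄ ≤ χ²₂,α), then a one-step reweighting keeps points with squared
robust distance ≤ χ²₀.₉₇₅(2) and recomputes mean and covariance (with
the 0.975 consistency factor). Only the center feeds the projection
detector, so the scatter corrections do not move outlier flags. A
collinear optimal subset sets a degeneracy marker; the center is still
returned and the skipped pipeline proceeds (the rotating-outlier example
depends on this). The deliberately *naive* removal baseline in the
planted-outlier study instead flags points by raw MCD distances at
maximal-breakdown coverage ⌊(n+3)/2⌋ and applies the uncorrected t-test
— the practice the skipped critical value exists to fix; this raw-
distance form is what reproduces the reported ≈0.4 type-I inflation.

## Inference

**Percentile bootstrap.** B pair resamples (default B = 1000); a
resample with a constant margin is invalid and redrawn (bounded by 100·B
attempts). Bounds are the order statistics ⌊αB/2⌋+1 and B−⌊αB/2⌋
(1-based) of the sorted statistic. The small-sample *adjusted* variant
fixes B = 599 and uses Wilcox's n-dependent indices ((7,593) for n<40,
(8,592) for n<80, (11,588) for n<180, (14,585) for n<250, else
(15,584)); it is the default for the variance-homogeneity test and
optional for correlations — the exact indices of the original
variance-homogeneity routine are not published, so this table is an
informed substitution. For skipped statistics the cleaned pairs are
resampled with the plain estimator; detection is not re-run per
resample. H0 is rejected when 0 lies outside the interval.

**Henze–Zirkler.** Standard statistic with smoothing parameter
β = ((n(2p+1))/4)^{1/(p+4)}/√2, p = 2, maximum-likelihood (1/n)
covariance, lognormal null approximation for p. Matches
`pingouin.multivariate_normality` to numerical precision (asserted in
the tests).

**Variance homogeneity vs Levene.** The bootstrap test resamples pairs
and builds the adjusted CI of var(x*) − var(y*). Levene is the classical
mean-centered form (|v − mean| ANOVA, df (1, 2n−2)) via
`scipy.stats.levene`; mean-centering is retained deliberately because
its outlier sensitivity is the point of the comparison.

**Conditional moments.** Five equal-count bins on the conditioning
margin (no binning rule is canonical; quantile bins keep per-bin counts
balanced), per-bin mean and unbiased variance of the other margin, both
directions. Note the within-bin variance includes the spread of the
conditional mean across the bin (≈ ρ²·var(x | bin) under a bivariate
normal), which matters for wide tail bins.

## Simulation design

Populations are standard bivariate normal with correlation ρ.
Contaminated populations replace round(0.1·n) randomly-positioned points
with draws from a unit-variance normal centered at [6, 0] (marginal) or
[6, 6] (bivariate) with correlation −ρ; at ρ = 0 the bivariate mixture
has population correlation 3.24/4.24 ≈ 0.764 by the mixture-moment
identity, which the harness reproduces empirically. Samples are drawn
directly from the model rather than subsampled from a pre-generated
parent pool — the two procedures are distributionally identical. All
methods are evaluated on the same draws, so method contrasts are paired;
effect-size bias uses Bonferroni-adjusted percentile CIs of r − ρ
(α = 0.05/14 for the 14-size grid), and method comparisons bootstrap the
median paired difference at the same adjusted level. Rejection-rate
contrasts between methods use a two-proportion z-test with Bonferroni
adjustment in place of the specialised discrete-case procedure the
original comparison used.

The planted-outlier study (n = 10) draws ten independent standard-normal
pairs and replaces one random observation: univariate case, second
coordinate from N(0, variance 3) — an SD-3 reading and a both-margins
variant are selectable, and shift the skipped rates by well under one
Monte-Carlo standard error; bivariate case, a draw with covariance
[[3, 4.5], [4.5, 9]].

**Problem sizes.** Vectorised Pearson-only grids run the full study
scale (10,000 replicates × 14 sizes). Skipped-correlation grids default
to 2,000 replicates on sizes {10, 20, 50, 100, 200}: the skipped
pipeline costs an MCD fit plus an O(n²) projection per replicate, and at
this scale the binomial standard error of a ~4 % rate (±0.4 points per
size) is already several times smaller than the tolerances being
checked. The planted-outlier comparisons run at the full 10,000
replicates via the batched exhaustive-MCD path. The CLI exposes
`--reps` and `--n-grid` to run any scenario at full scale.

## Numerical choices and edge cases

* Determinant ties in the exhaustive MCD resolve to the first subset in
  lexicographic order (deterministic).
* Degenerate projection directions (point at the center, zero spread)
  contribute no constraints.
* r = ±1 reports p = 0 and T = ±∞; the skipped test treats it as a
  rejection when m ≥ 3.
* Skipped estimates are *undefined* (NaN, h = 0, reason code) when
  removal leaves fewer than 3 points or a constant margin; simulation
  harnesses count these as non-rejections and tally them separately.
* All simulations derive per-block streams from `numpy` `SeedSequence`
  spawning, so runs are reproducible per seed and blocks are
  independent.

## What the generators do and do not emulate

The synthetic populations are exactly the study's model: Gaussian cores
with point-mass-located Gaussian contamination at fixed displacement and
fixed 10 % rate. Real data differ in ways the harness does not model —
skewed or heavy-tailed margins, heteroscedasticity, clustered outliers,
measurement floors/ceilings — so passing the calibration tests shows
correctness of the implementation under the stated model, not that the
5 % level is guaranteed on arbitrary data. The assumption checks
(normality, variance homogeneity, conditional moments) exist precisely
to probe those departures on real samples.

## Known limitations

* Bivariate only (p = 2); no partial or multi-variable extensions.
* The skipped decision rule supports α = 0.05 only.
* The MAD-median projection variant reproduces the qualitative
  inflation of its published error rate but sits below its reported
  magnitude; the box-plot variant (the recommended rule) matches.
* FAST-MCD for n > 12 is stochastic; with 50 starts it matched or beat
  scikit-learn's MinCovDet determinant in testing, but global optimality
  is not guaranteed.
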