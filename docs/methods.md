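# Methods

This note documents the models, conventions, and numerical choices behind
`kipuka`, and what the synthetic tests do and do not establish about real
surveys.

## Dispersion metrics and the null model

For a community C on a distance matrix `d` (patristic branch-length sums, or
absolute differences of log trait values):

- MPD = mean of `d(i, j)` over all unordered pairs in C;
- MNTD = mean over members of the minimum distance to any other member.

The null resamples |C| species uniformly without replacement from the
regional pool ("richness" null, presence/absence only — the surveys the
package emulates record no abundances) and recomputes the metric, 1000 times
by default. Conventions, fixed because rank arithmetic must be reproducible:

- `rank = #{null ≤ observed}`, ties counting toward the rank (the
  conservative choice; ties are measure-zero for continuous distances);
- `p = rank / n_reps` (not `(rank+1)/(n_reps+1)`), so rank 156 of 1000 reads
  as p = .156;
- verdict: *clustered* if p < .025, *overdispersed* if p > .975 (two-tailed
  5%), else *neutral*. With rank uniform on {0, …, n_reps} under the null,
  each tail triggers with probability 25/1001 ≈ 2.5%, which the calibration
  test verifies over 4,000 neutral communities.
- degenerate nulls (community = pool) have zero spread: SES is reported as
  NaN with a warning and the verdict falls back to the observed value's
  position (equal → neutral).

Blomberg's K uses the contrast-based form
`K = (MSE0/MSE) / [(tr(V) − n/(1ᵀV⁻¹1))/(n−1)]` with V the Brownian
covariance; all V⁻¹ quantities come from a linear-time pruning pass
(verified against dense GLS in the tests), so K on a 641-tip tree costs
microseconds, which matters because K enters every reference-table row
twice.

## Trait-evolution models

BM tip values are jointly normal, mean `z0`, covariance `σ²·C` with `C` the
shared root-to-MRCA path lengths. The OU covariance for tips i, j with MRCA
at depth `s` and tip depths `T_i, T_j` is
`σ²/(2α)·e^{−α(T_i+T_j−2s)}·(1−e^{−2αs})`, with tip means
`z0·e^{−αT} + θ(1−e^{−αT})`; α → 0 recovers BM, and both limits are tested.
BM likelihoods and fits use the pruning pass (the BM ML fit is closed form:
GLS mean and `σ̂² = Q/n`); OU likelihoods use a dense Cholesky solve, which
is exact and fast at the tree sizes where fitting happens.

OU fitting maximises over (log σ², log α, θ) with L-BFGS-B from five
jittered, seed-controlled starts; the root state is tied to the optimum
(z0 = θ, a stationary-style start) but still counted, so AIC uses k = 4
(k = 2 for BM). Because σ² and α trade off on a single tree, simulation
rates are chosen by a bounded-α profile: OU is refit with the α cap swept
over 10 log-spaced bounds in [0.01, 1], and the estimates are read at the
smallest bound past which every subsequent per-step log-likelihood gain is
below 2 units (an AIC-equivalent gain; the rule is exposed as
`select_plateau` and unit-tested on synthetic profiles). A profile still
gaining at the last bound returns that bound's fit flagged `saturated`.

## Assembly simulation

Regional pools are forward birth–death simulations from a crown pair,
stopped the moment the extant count reaches `n` (641 by default), with the
present extended past the last speciation by a uniform fraction of one
expected waiting time so terminal branches are never zero; extinct lineages
are pruned. Complete extinction restarts the simulation; persistent failure
raises an error rather than returning silently.

Communities assemble by sequential proposal: a candidate is drawn uniformly
from the pool (every regional species has an equal chance to colonise) and
accepted with probability

- filtering: `w = exp(−(x − x_opt)² / (t·w₀))`
- competition: `w = 1 − exp(−min_j (x − x_j)² / (t·w₀))` over current
  residents (limiting similarity is a nearest-neighbour phenomenon; the
  first colonist is always accepted)
- neutral: `w = 1`

with weights clamped to [1e-12, 1] and a proposal budget of 10,000 per
community slot. `x_opt` defaults to the pool trait mean, which makes
filtering detectable through variance reduction without shifting the mean.
Both kernels converge to neutral as t → ∞ (tested distributionally).

**Kernel width.** The strength parameter is defined on t ∈ [1, 60] (small =
strong). The kernel width multiplier `w₀ = KERNEL_WIDTH = 0.2` maps t onto
the squared-log-height scale of the emulated system, whose stationary trait
variance is σ²/2α ≈ 2.3: with w₀ = 0.2 the prior spans essentially
deterministic acceptance-by-trait at t = 1 to near-neutral assembly at
t = 60. This constant was calibrated once, on a pilot of 250 simulations
per model, to give the documented classifier error structure (competition
far easier to recognise than filtering or neutrality, overall error around
one in five); it is a property of the simulator's trait scale, not a
user-facing dial.

**Reference table.** For each model, `n` rows (10,000 by default; the
acceptance runs use 2,000 per model to fit a desk-scale budget): draw
t ~ U(1, 60), λ ~ U(0.05, 2.0), μ = f·λ with f ~ U(0, 0.8); simulate the
pool and OU traits at the study rates (σ² = 0.92, α = 0.2, θ = 4.8 log-cm,
i.e. a ~120 cm optimum); assemble one community with richness drawn from
the observed richness set (9–20); compute the 30 statistics. Failed
simulations are resampled and counted. Tables are bit-for-bit reproducible
from (seed, priors, conditions).

## Summary statistics

The 30-statistic registry (see `registry_manifest()`) spans local trait
moments (mean, variance, skewness, kurtosis, range, median), regional mean
and variance, local/regional mean- and variance-ratios, phylogenetic
dispersion of the community on the regional tree (MPD, MNTD, their SES
against a 64-replicate internal null, Faith's PD and PD per species, mean
branch length, tree height), phylogenetic signal (Blomberg's K, local and
regional), tree shape (normalised Colless imbalance, the Pybus–Harvey gamma,
richness and richness ratio), distance–trait coupling (patristic × trait
distance correlations, local and regional pairs), and trait-spacing extremes
(min/max nearest-neighbour trait gap, Gini of cm-scale heights, local/
regional MPD ratio). The internal SES nulls use 64 replicates rather than
1000: SES enters only as a classifier feature, where that noise is
tolerable, and the full-precision test lives in the dispersion module.
Degenerate inputs (zero-variance traits, zero-spread nulls) produce sentinel
zeros, never NaN, so every simulated row is usable. The registry is isolated
in one module so an alternative list can be swapped in without touching
inference.

## Inference

The classifier is a 1000-tree random forest (scikit-learn) on the 30
statistics. OOB errors (overall and per label) come from the forest's
out-of-bag votes. Statistic importance is permutation importance evaluated
on each tree's out-of-bag rows (averaged over a fixed subset of trees for
throughput, 200 by default, deterministic under the seed).

Rejection ABC accepts exactly `n_accept = 100` reference rows — the
k-nearest form of "accept the 100 closest", rather than an ε-threshold —
by Euclidean distance on the top-10 most important statistics, each scaled
by its SD across the reference rows; cutoff ties are broken by a seeded
shuffle. Only rows simulated under the best-supported model are used.
The posterior sample of t is summarised by its median and by both 90% and
95% highest-density intervals (shortest contiguous window containing
⌈mass·n⌉ sorted points); both masses are emitted because reporting
conventions differ between methods and results contexts.

## Geography regressions

Per-community support for each model is regressed on richness, log area,
log isolation, and elevation (area and isolation span 2–3 orders of
magnitude; the log transform is the default and is configurable). The
battery is: each single covariate, each pairwise interaction (`a * b`), and
the full additive model — 11 formulae × 3 responses = 33 OLS fits, flagged
at α = 0.05 with no multiple-testing correction; the output records how
many tests were run so readers can judge the flag count. Support values are
treated as plain responses; no logit transform is applied, matching common
practice for descriptive support regressions at n = 19.

## Synthetic surveys

`SyntheticConfig` defaults are the study conditions: 641 regional species,
OU log-height with σ² = 0.92, α = 0.2, θ = 4.8; 19 communities with
richness uniform on 9–20 (the emulated survey reports only the range, so
uniform is assumed); area log-uniform on 700–114,100 m², isolation
log-uniform on 17.65–2,137 m, elevation uniform on 1,358–1,678 m, drawn
independently (weak geography effects are the honest null; planted effects
are opt-in). Default birth–death rates for a fixed pool are λ = 0.5,
μ = 0 — a clean Yule pool; reference-table rows draw rates from the priors
instead. BM roots at 0 on the log scale; OU roots at θ. Trait values are
generated on the log scale; the writer also emits cm-scale heights.
`synthesize_support_table` builds softmax-based support tables with planted
linear effects directly, so regression calibration and power can be tested
without running the full inference chain.

What the generator does *not* emulate: spatial structure of the lava
matrix, within-species trait variation, abundances, survey detection error,
and any correlation among geography covariates. Passing tests therefore
demonstrate internal correctness and recoverability under the stated
generative model, not robustness to those real-data complications.

## Problem sizes and determinism

Default sizes follow the emulated study (10,000 simulations per model,
1000 null replicates, 1000 trees). The packaged acceptance checks run
2,000 simulations per model and the test suite scales Monte-Carlo loops to
hundreds of replicates; those sizes are the package's own desk-scale
choices and are stated where used. All randomness flows from explicit
seeds; the pipeline derives per-stage seeds from one master seed by fixed
offsets and records them in its manifest, and reference tables and full
pipeline outputs are byte-reproducible under a fixed seed.

## Known limitations

- The 30-statistic registry is this package's fixed choice of
  information-equivalent statistics; other implementations of the same
  workflow use their own lists, so absolute importance rankings are not
  comparable across implementations.
- The assembly kernels are documented stand-ins with a calibrated width;
  estimated t values are interpretable on this package's scale (prior
  U(1, 60), small = strong), not as universal constants.
- OU fitting on a single ultrametric tree cannot jointly identify σ² and α;
  the bounded-α profile makes the choice reproducible, not unique.
- ABC intervals at 9–20-species communities are intrinsically broad; the
  tests check ordering (strong vs weak truth), not calibrated coverage.
- Real-data mode assumes the megaphylogeny's branch lengths are given and
  correct; no dating or calibration is performed.
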