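# Methods

## Estimator

All nonparametric quantities start from the pooled mid-ranks of the n = n₀ +
n₁ observations. The AUC estimate AUĈ = (R̄₁ − R̄₀)/n + ½ is the normalized
Mann-Whitney U statistic; ties are handled everywhere by mid-ranks /
half-weights (consistent with the normalized distribution function
F(x) = P(X < x) + ½P(X = x)), never by random breaking. Degenerate samples
(all values tied) are legal and yield AUĈ = 0.5 with zero estimated
variance — correctly, since a degenerate marker has zero sampling
variability.

## Variance estimators

Three variance routes feed the intervals:

* **Placement (structural-component) SE.** The placement of a case is the
  fraction of controls it exceeds (ties half-weighted), and vice versa; both
  vectors average to AUĈ. `se_empirical` returns
  √(S₁²/n₁ + S₀²/n₀) with S_i² the (n_i − 1)-denominator variances of the two
  placement vectors. This is the standard estimator asymptotically
  equivalent to the Brunner-Munzel rank variance, and it backs the LT and
  M-W intervals. The LT/M-W reference results are insensitive to the choice
  among these asymptotically equivalent variants at the sample sizes
  studied (coverage differences are inside the Monte-Carlo noise).

* **Bamber's unbiased variance.** The exact variance of AUĈ is
  [Var(w) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]/(n₀n₁), with w the 0/½/1
  comparison kernel, Q₁ = P(two cases both beat one control), Q₂ = P(one
  case beats two controls). `var_bamber` plugs in the unbiased U-statistic
  estimates of Q₁, Q₂ and mean(w²), and divides the bracket by
  (n₀−1)(n₁−1) rather than n₀n₁: the downward bias of the squared point
  estimates then cancels exactly, making the estimator unbiased (verified
  in the test suite by comparing E[V̂] with the true sampling variance).
  The naive n₀n₁ plug-in underestimates the variance by the factor
  (n₀−1)(n₁−1)/(n₀n₁) — about 10% at n = 40, enough to shift Bamber-interval
  coverage by 1.5 percentage points. Q₁/Q₂ are computed from sorted counts
  in O(n log n) and match exhaustive triple enumeration exactly.

* **Maximum variance.** σ̂²max = AUĈ(1−AUĈ)/(0.75n−1), Bamber's asymptotic
  bound for continuous markers with monotonic posterior and balanced
  groups. This is what makes the modified Wald intervals summary-computable
  and deliberately conservative; its breakdown under strongly unbalanced
  allocation (the bound assumes n₁ ≈ n₀) is exactly what the 1:9 robustness
  grid exposes.

* **Binormal.** AUC\* = Φ((x̄₁−x̄₀)/√(s₀²+s₁²)); its SE comes from a
  first-order delta method with Var(s_i²) = 2σ_i⁴/(n_i−1) under normality.
  The delta method was chosen over resampling because it is deterministic,
  exact to first order under the (here true) generating model, and cheap;
  the test suite checks it against the empirical spread of AUC\* across
  replicates. Unlike iterative binormal fitters, this closed form stays
  computable even for completely separated samples.

## Interval construction and reporting

The ten intervals and their metadata (range-preserving; computable at
AUĈ = 1) are in `aucci.intervals`. Conventions that are deliberate choices:

* The Clopper-Pearson success count k = round(AUĈ·n) rounds halves away
  from zero (120.5 → 121) so results are platform-independent. The interval
  is implemented in the F-quantile form and tested to 1e-10 against the
  beta-quantile form.
* Agresti-Coull at AUĈ = 1 produces a finite formula value but is flagged
  non-computable, matching the method's documented behaviour in this
  family; the uncorrected modified Wald degenerates to [1, 1] and is
  likewise flagged.
* Wilson-cc limits are truncated into [0, 1] (standard continuity-corrected
  score behaviour), so all four range-preserving methods satisfy 0 ≤ lower
  ≤ upper ≤ 1 as a testable invariant.
* Reporting clips only the *upper* limit to 1. In the designs studied
  (AUC ≥ 0.7) lower limits never go negative; if one ever does, a warning
  is logged and the limit left untouched. Coverage uses the reported
  interval; since every truth is below 1, clipping never changes
  containment (a documented no-op).
* Summary mode refuses LT, M-W, binormal and Bamber. Bamber's *interval*
  formula needs only AUĈ, but its variance estimator needs the individual
  values, so it cannot honestly be produced from (AUĈ, n₀, n₁).

## Simulation design

Controls are N(0, σ₀²), cases N(Δ, σ₁²) with Δ = Φ⁻¹(AUC₀)·shift_sd and
shift_sd = √(σ₀²+σ₁²) by default, so the population AUC equals AUC₀
exactly. Defaults mirror the design under study: AUC₀ ∈ {0.7, 0.8, 0.9},
n ∈ {40, 100, 200}, 1:1 allocation, σ₀ = σ₁ = 1, α = 0.05 two-sided,
10 000 repetitions per truth.

* **Spike averaging.** Coverage and length are averaged over the three
  truths AUC₀ − 0.01, AUC₀, AUC₀ + 0.01 to smooth the sawtooth coverage of
  discrete statistics.
* **Non-computable runs** (AUĈ = 1 for LT/M-W, k = n for C-P) are counted
  (`n_failed`) and excluded from both coverage and length denominators, so
  the handling is visible rather than silent.
* **Allocation.** A ratio r₁:r₀ assigns n₁ = round(n·r₁/(r₁+r₀)) cases
  (1:2 at n = 40 gives 13/27).
* **Variance heterogeneity.** The robustness study varies the case
  variance σ₁² ∈ {0.5, 2, 3} while *keeping the case shift at the
  homoscedastic scale √2* (`shift_sd` pinned). The realized AUC then
  deliberately drifts from the nominal truth the intervals are checked
  against — this mismatch, not the heteroscedasticity itself, is what
  degrades rank-based coverage, and it is the stress the study design
  encodes. With a per-σ consistent shift the realized AUC equals the
  nominal one and no rank-based interval loses any coverage (the package
  supports both via `shift_sd`).
* **Ordinal robustness.** Five categories cut at the 20/40/60/80th
  *empirical pooled percentiles of each run* (cut points re-estimated per
  repetition; `numpy` linear-interpolation quantiles).
* **Power** is rejection of H₀: AUC = AUC₀ by exclusion of AUC₀ from the
  reported (clipped) two-sided interval; at AUC₁ = AUC₀ it estimates the
  type-I error. All methods are evaluated on the same samples (common
  random numbers), so power *differences* are estimated far more precisely
  than the curves themselves. The power study uses the full 10 000
  repetitions per grid point: the max-over-grid difference statistic picks
  up about 2 percentage points of upward Monte-Carlo bias at 2 000
  repetitions.
* **RNG.** Each scenario cell carries an integer seed; `run_coverage`
  spawns one independent child stream per truth, so cells and truths can be
  run in any order or subset with bitwise-identical results.
* **Vectorization.** The batch path computes mid-ranks row-wise over a
  (repetitions × n) matrix with a hand-written accumulate-based kernel
  (~10× faster than the general-purpose scipy `rankdata` over an axis, and
  exact under ties); placements come from the identity
  pooled-midrank − within-group-midrank = opposite-group count. The batch
  path is tested per-repetition against the scalar estimators and interval
  constructors to 1e-10.

## What the generator does and does not emulate

The generator reproduces the evaluation conditions: normal (or
quantile-binned ordinal) markers, exact control of the population AUC,
case-control sampling. It does not emulate skewed or heavy-tailed markers
(rank invariance makes the rank-based intervals indifferent to any
monotone distortion, and the suite verifies exact invariance under exp),
covariates, verification bias, or clustered data. Passing tests therefore
speak to interval behaviour under a correctly specified two-group model at
the stated sizes, not to those complications.

## Known limitations

* The binormal interval here is the delta-method version; software that
  fits the binormal model iteratively can fail or differ on awkward
  samples (the published worked example reports exactly such a failure),
  and our closed form's computability at empirical separation is a
  deliberate difference.
* The modified Wald variance bound assumes balanced groups; the 1:9 grid
  shows the consequence (median coverage ≈ 76–78%), so the Wald intervals
  should not be used for strongly unbalanced designs — that finding is the
  point, not a defect.
* Coverage comparisons against published values carry ±1–1.5 percentage
  points of slack: Monte-Carlo noise at 10 000 repetitions plus the
  unprinted variance-estimator variant behind the LT/M-W reference
  implementation.
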