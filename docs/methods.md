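# Methods

This note records the modeling assumptions, default parameters, and
numerical conventions behind `oculater`.

## 1. The LATER / recinormal model

A saccade latency is modeled as the first-passage time of a linearly
rising decision signal: starting from a baseline level `θ0`, the signal
climbs at rate `R` until it reaches a threshold `θT`, so

```
T = θ / R,   θ = θT − θ0,   R ~ Normal(µ, σ²)   (rate varies across trials)
```

Promptness `1/T` is then Gaussian with mean `µ/θ` and SD `σ/θ`, giving the
recinormal density and CDF

```
f(t) = θ / (t² σ √(2π)) · exp(−(θ/t − µ)² / (2σ²))
F(t) = Φ( µ/σ − (θ/σ)/t )
```

Assumptions inherited from this form:

- **No early component.** Express/anticipatory saccades are not modeled as
  a second accumulator; upstream preprocessing removes latencies outside
  100–450 ms instead.
- **Truncated negative rates.** `R ≤ 0` (no response) has probability
  `1 − Φ(µ/σ)`. Sampling rejects such draws; the density is used
  unnormalized because in the empirical regime `µ/σ ≳ 6` the missing mass
  is < 10⁻⁹. A `RuntimeWarning` is emitted when `µ/σ < 4`, where the
  approximation error exceeds ~3×10⁻⁵.
- **θT is arbitrary.** Only `θ/µ` and `θ/σ` are observable, so `θT` is
  fixed (default 1) and all threshold-unit parameters are reported
  relative to it. Refitting with a different `θT` rescales every parameter
  and leaves log-likelihood, BIC, and the implied distributions unchanged.

### Scale degeneracy of the baseline variant

In the `vary_theta0` variant (per-condition `θ0_c`, shared `µ, σ`), the
mapping

```
θ0_c → θT(1−α) + α·θ0_c,   µ → αµ,   σ → ασ        (all conditions at once)
```

leaves every condition's density unchanged for any feasible `α > 0`, even
with `θT` fixed. The likelihood is therefore *exactly flat* along this
one-dimensional ridge: data determine each condition's `µ/θ_c` and
`σ/θ_c`, which is 2·(#conditions) quantities for (#conditions + 2)
parameters. Consequences:

- BIC, information weights, and variant selection are ridge-invariant and
  fully identified.
- Absolute `θ0` values (and percentage "baseline reductions" between
  conditions) are meaningful only relative to a normalization. The fitter's
  moment-based initialization sets `µ = θT · min_c(mean promptness)`, which
  anchors the fastest condition's baseline near 0; the optimizer, having no
  gradient along the ridge, stays near that canonical position. Parameter-
  recovery checks therefore use generating parameters in the same canonical
  form (every generating scenario is exactly scale-equivalent to one).

## 2. Constrained maximum-likelihood fitting

`fit_variant` / `ConstrainedLaterModel` maximize the joint log-likelihood
over (per-condition varied parameter, two shared parameters):

- **Parameterization.** `k = #conditions + 2` free parameters;
  `BIC = k·ln(n) − 2·logL` with `n` = total trials in the joint fit (the
  three variants see identical data, so any consistent `n` preserves weight
  ordering).
- **Bounds.** `θ0 ∈ [0, 0.999·θT]`, `µ ∈ [10⁻⁸, ∞)`, `σ ∈ [10⁻⁹, ∞)`
  (L-BFGS-B box constraints).
- **Initialization.** Moment estimates from the promptness distribution
  (mean and SD of `1/t` per condition mapped through `θ`), with lognormal
  jitter for `n_starts = 10` multi-starts.
- **Tie-breaking.** Among converged starts: highest log-likelihood, then
  lexicographically smallest parameter vector — fits are reproducible for
  a given seed.
- **Floors.** ≥ 2 conditions with ≥ 20 trials each (configurable); fewer
  raises immediately rather than returning an unstable fit.
- The fitted density is evaluated on window-filtered data without
  renormalizing for the window: with the default parameters < 2% of mass
  lies outside 100–450 ms, and all variants incur the same approximation.

## 3. Model comparison

BIC information weights `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`,
`Δ_i = BIC_i − min_j BIC_j`. Uncertainty comes from a bootstrap
(default 100 iterations) that resamples trials with replacement
*within each condition* (stratified, preserving per-condition counts),
refits all three variants per iteration, and reports percentile 95%
intervals of the weights. Failed iterations are retried with fresh
resamples up to a cap. Fits and comparisons are always per participant,
never pooled.

## 4. Default generative parameters

`default_study_params()` is calibrated analytically from the
recinormal mean `E[T] ≈ (θ/µ)(1 + (σ/µ)²)` against the target condition
means 187 / 192 / 192 / 228 ms; nothing was tuned against test outcomes.

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `theta_t` | 1 | threshold units | arbitrary scale anchor |
| `mu` | 0.004347 | θT/ms | sets the ~187 ms fastest condition mean |
| `sigma` | 0.000696 | θT/ms | `µ/σ ≈ 6.25`, typical reciprobit slope |
| `theta0_by_condition` | 0.2074 / 0.1861 / 0.1861 / 0.076 | θT | no-choice high/low, with-choice chosen/non-chosen baselines |
| `p_choose_high` | 0.95 | — | near-exclusive high-reward choices |
| `delta_theta0_inhibit` | 0.076 | θT | extra baseline drop after a choice-trial toward the non-chosen side (~18 ms) |
| `cue_relief` | 0.5 | — | fraction of the baseline deficit removed by pre-cueing |
| `contrast_mu_scale` | 0.873 / 1.0 / 1.02 | — | rate scaling by target contrast |
| `difficulty_deficit_scale` | 0.7 / 1.0 / 1.4 | — | scales the non-chosen deficit with discrimination difficulty |
| `wrong_target_rate` | 0.005–0.10 | — | wrong-direction saccades by difficulty |
| `p_too_early` | 0.01 | — | anticipations (< 100 ms) |
| `p_recording_error` | 0.03 | — | tracker losses (no latency recorded) |
| `deadline_ms` | 500 | ms | responses later than this are misses |

The with-choice low-reward mean (≈228 ms) is not a separate parameter: it
*emerges* as the 50/50 mixture of after-single (`θ0 = 0.076`, ≈218 ms) and
after-choice-inhibited (`θ0 = 0`, ≈236 ms) states, which simultaneously
produces the ~18 ms sequential (N−1) effect.

**Scope and limits of the generator.** It emulates block composition,
choice resolution, sequential inhibition, cue relief, contrast and
difficulty effects, anticipations, misses, and recording errors — enough
to drive every analysis stage end to end. It does not emulate: learning or
session drift, express-saccade modes, gaze-position noise, microsaccades,
or between-participant parameter variability (all participants share one
parameter set; participant CIs on synthetic cohorts reflect sampling noise
only). Pre-cueing is encoded at block granularity (separate cued/uncued
blocks), since per-block constancy of design fields is a schema invariant.

## 5. Preprocessing conventions

- Latency window 100–450 ms, **inclusive** at both bounds; trials without
  a recorded latency (recording errors) are counted separately from window
  exclusions.
- N−1 labels (`prev_type`, `prev_direction`) never cross block boundaries;
  for a preceding choice-trial the comparison direction is the *chosen*
  side. Input must be ordered by trial index within block.
- Misses partition into too-early / too-late / wrong-target among
  responded non-hits; `no_response` is tracked separately.

## 6. Statistics conventions

- **JZS Bayes factors** by direct quadrature of the Rouder one-sample
  integrand, Cauchy prior scale `r = √2/2` (pinned by matching the
  reproducible reference value; the independent pingouin implementation
  agrees to ~10⁻⁴ relative).
- **Wilcoxon signed-rank**: `W` = sum of negative-difference ranks; `z`
  from the normal approximation *without* continuity correction (this
  convention reproduces the reference two-decimal Z for the all-positive
  n = 8 case); exact two-sided p for `n ≤ 25` with untied ranks from the
  null distribution computed by dynamic-programming convolution —
  mathematically identical to enumerating all 2ⁿ sign patterns. Zero
  differences are dropped before ranking.
- **ANOVA** delegates to pingouin (Greenhouse–Geisser ε always reported);
  zero-variance factors are mapped to `F = 0, p = 1` instead of NaN.
  Unbalanced or incomplete designs are rejected, not silently dropped.
- **Bonferroni**: `α/m` exactly; display rounding only at print time.

## 7. Known limitations

- Absolute `θ0` values depend on the normalization described in §1; only
  ridge-invariant quantities (weights, BIC differences, implied latency
  distributions) are comparable across software.
- The exact-p Wilcoxon path is disabled when ranks tie (midranks make the
  DP lattice irregular); the normal approximation is always reported.
- The bootstrap uses percentile intervals; no BCa correction.
- The window-truncation of the likelihood is ignored (see §2); for
  parameter regimes with heavy mass outside the window, fitted parameters
  would be biased.
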