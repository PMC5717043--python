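# oculater

Saccade-latency analysis with the LATER model: simulation of reward/choice
eye-movement experiments, latency preprocessing, constrained recinormal
maximum-likelihood fitting, and bootstrap BIC model comparison.

## Scientific background

When people repeatedly choose between two targets that pay different
rewards, they almost always pick the higher reward — and saccades to
less-rewarded targets become markedly slower. Strikingly, this latency cost
appears only when choices are actually interleaved among the single-target
trials: reward differences alone barely move latencies. The mechanistic
question is *where* in saccade preparation this selection acts.

The LATER model (Linear Approach to Threshold with Ergodic Rate) frames a
saccade latency `T` as the time a decision signal needs to rise linearly
from a baseline level `θ0` to a threshold `θT`:

```
T = θ / R,     θ = θT − θ0,     R ~ Normal(µ, σ²)
```

The rate of rise `R` varies across trials, so `1/T` (the "promptness") is
Gaussian and `T` follows the **recinormal** distribution

```
f(t) = θ / (t² σ √(2π)) · exp(−(θ/t − µ)² / (2σ²))
F(t) = Φ( µ/σ − (θ/σ)·(1/t) )
```

On a *reciprobit* plot (probit of the empirical CDF against `1/t`), data
from one condition fall on a straight line with slope `−θ/σ` and intercept
`µ/σ`. Fitting several conditions jointly while letting exactly **one** of
`{θ0, µ, σ}` vary across conditions (the other two shared) turns "where
does reward/choice act?" into a model-comparison problem:

- `vary_theta0` — conditions differ in the **baseline level** (pre-stimulus
  preparation);
- `vary_mu` — conditions differ in the mean **rate of rise** (evidence
  accumulation);
- `vary_sigma` — conditions differ in rate **variability**.

Variants are scored by BIC and compared with information weights
`w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)`, with confidence intervals from a
stratified bootstrap over trials. On data like those modeled here, the
baseline-level account wins: interleaving choices lowers `θ0` for
less-rewarded targets rather than slowing the accumulation itself.

## Worked example

Simulate a full single-participant session of the choice-context design
(10 single-target-only blocks, 20 blocks with 50% choice-trials), filter
latencies to the 100–450 ms analysis window, and ask which LATER parameter
explains the condition differences:

```python
import oculater as oc

params = oc.default_study_params()
trials = oc.simulate_experiment(oc.get_design(6), params,
                                n_participants=1, seed=42)

labeled = oc.label_previous_trial(trials)
kept, report = oc.apply_latency_window(labeled)
print(f"kept {report.n_kept}/{report.n_total} "
      f"({report.fraction_window_excluded:.2%} outside 100-450 ms, "
      f"{report.fraction_recording_error:.2%} recording errors)")

effects = oc.condition_effects(kept, ["choice_proportion"])
print(effects.aggregate.round(1).to_string(index=False))

conds = oc.later_conditions(kept)
comp = oc.bootstrap_compare(conds, n_boot=100, seed=0, n_starts=5)
print("best:", comp.best_variant)
print({k: round(v, 3) for k, v in comp.weights_mean.items()})

fit = comp.variant_fits_full_data["vary_theta0"]
print("reduction no-choice: %.1f%%"
      % oc.baseline_reduction(fit, "no_choice_high", "no_choice_low"))
print("reduction with-choice: %.1f%%"
      % oc.baseline_reduction(fit, "with_choice_high", "with_choice_low"))
```

Output:

```
kept 2897/3000 (0.73% outside 100-450 ms, 2.70% recording errors)
 choice_proportion  mean_low  mean_high  mean_diff  ci_low  ci_high  n_participants
               0.0     193.2      186.8        6.4     NaN      NaN               1
               0.5     226.0      195.7       30.4     NaN      NaN               1
best: vary_theta0
{'vary_theta0': 0.959, 'vary_mu': 0.041, 'vary_sigma': 0.0}
reduction no-choice: 16.5%
reduction with-choice: 90.5%
```

The signature pattern is visible directly: without interleaved choices the
low-reward latency cost is ~6 ms; with 50% choice-trials it grows to
~30 ms, and the bootstrap comparison attributes it to the baseline level
`θ0` (mean weight 0.96), with a much stronger baseline reduction in the
choice context. (CIs are undefined with a single participant.)

## Command line

The same stages are exposed as a console script:

```
oculater simulate  --experiment 6 --participants 2 --seed 1 --out trials.csv
oculater preprocess --in trials.csv --out kept.csv --report exclusions.json
oculater effects    --in kept.csv --out effects.csv
oculater fit-later  --in trials.csv --out fits.json
oculater compare    --in trials.csv --out comparison.json
oculater run-all    --config config.yaml            # full pipeline + manifest
oculater report     --manifest run/manifest.json    # markdown summary
```

`run-all` derives all stage seeds from one master seed and writes a
checksummed manifest; rerunning the same config reproduces every output
file byte for byte.

## Behavioral statistics

`oculater.stats` bundles the tests used alongside the model: paired t-tests
with JZS Bayes factors (numerical integration, Cauchy prior scale √2/2,
cross-checked against pingouin), repeated-measures and mixed ANOVA with
Greenhouse–Geisser correction (via pingouin), Wilcoxon signed-rank with an
exact small-sample null distribution and the uncorrected normal
approximation, Friedman tests, and Bonferroni-adjusted alphas.

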