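# readscan

Reading eye-movement profiling for two-group studies (e.g. adult readers
with and without dyslexia reading standardized multi-line paragraphs).
The package turns per-trial fixation/saccade/blink event streams plus a
word-layout description into a comprehensive oculomotor reading profile,
and ships a synthetic scanpath generator so the entire pipeline can be
exercised and validated without any recording hardware or copyrighted
stimulus texts.

## What it computes

Given cleaned, word-assigned trials the pipeline produces:

* **Global metrics** per trial: mean/median fixation duration, total scan
  path (deg), mean/median/SD saccade amplitude, reading duration, words
  per minute.
* **Local (word-based) metrics**: first-run dwell time (gaze duration
  Σ of fixation durations during the first visit to a word neither visited
  nor skipped before), first-pass skip ratio, ratio of visited words,
  fixations per word, number and probability of regressions.
* **Saccade taxonomy**: forward, regression, return-sweep, undersweep
  (short-landing sweep followed by a leftward corrective), blink-adjacent,
  and *directional deviations* — saccades with angle 35°–145° above or
  below the horizontal reading axis after excluding sweeps, undersweeps
  and blink-adjacent saccades; plus line-initial fixation detection (the
  first fixation on one of a line's first two words without a leftward
  corrective), which lacks parafoveal preview and indexes pure lexical
  processing time.
* **Scanpath similarity**: duration-weighted sequence alignment (Scasim)
  with gap cost = fixation duration and substitution cost
  `(d_a + d_b) − 2·min(d_a, d_b)·γ^dist` (γ = 0.83 per degree),
  normalized by summed viewing time, then non-metric MDS → GMM/BIC cluster
  count → k-means → χ²/exact cluster-by-group association per text-font
  pair.
* **Group statistics**: unbiased Hedges' *g* with exact noncentral-*t*
  95% CIs (sign convention: negative = dyslexia group larger/longer),
  pooled and one-sample *t*-tests with Bonferroni correction, JZS Bayes
  factors (Cauchy width 0.7), robust percentage-bend correlations (20%
  bending), proportion-of-consistent-readers, and the deviation-coded
  gamma-GLMM design matrix with likelihood-ratio model comparison
  (solver delegated to any mixed-model backend).

## Worked example

```python
from readscan import SampleStats, hedges_g, independent_t

control  = SampleStats(mean=12.84, sd=2.53, n=32)   # processing-speed scores
dyslexia = SampleStats(mean=9.40,  sd=2.27, n=35)

res = hedges_g(control, dyslexia)
t, df, p = independent_t(control, dyslexia)
print(f"g = {res.g:.4f}, 95% CI [{res.ci95[0]:.4f}, {res.ci95[1]:.4f}]")
print(f"t({df}) = {t:.2f}, p = {p:.2g}")
```

prints

```
g = 1.4182, 95% CI [0.8915, 1.9693]
t(65) = 5.87, p = 1.6e-07
```

i.e. a large, significant processing-speed advantage for the control
group: the groups differ by ~1.4 pooled standard deviations and the CI
excludes zero.

End-to-end on synthetic data:

```python
from readscan import CohortSpec, PipelineConfig, analyze_cohort, simulate_cohort

spec = CohortSpec(n_control=10, n_dyslexia=10, n_texts=9, master_seed=1)
trials, layouts = simulate_cohort(spec)          # 360 trials, 18 text-font pairs
result = analyze_cohort(trials, layouts, PipelineConfig(cohort=spec, seed=1))
print(result.effect_table)                        # Hedges' g per metric
print(result.significant_pair_fraction)           # cluster-group association
```

With the default reader profiles (fixation-duration medians 202 vs 224 ms,
line-initial inflations +14 vs +32 ms, deviation rates 0.44 vs 1.00 per
trial, downward deviations for the dyslexia profile) the recovered group
medians land on the generating parameters (e.g. 203.5 vs 225.7 ms median
fixation duration at seed 1) and every profiled metric shows the expected
direction of effect.

There is also a thin CLI:

```bash
readscan simulate --out sim/ --seed 1          # events TSV + layout JSONs
readscan run --out run/ --seed 1               # full pipeline + manifest
readscan validate sim/events.tsv
```

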