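# Methods

## Scope and data model

The unit of analysis is a *trial*: one participant silently reading one
multi-line text in one font, represented as time-ordered fixation, saccade
and blink events in trial-relative milliseconds and screen pixels (origin
top-left, y downward), together with a display geometry (default 1024×768
px, 0.38 mm pixels, 70 cm viewing distance — 1° of visual angle ≈ 32 px)
and a text layout of per-word bounding boxes. Saccades are always
re-derived from the retained fixations rather than trusted from the input
stream, because event cleaning invalidates recorded saccade pairings.

## Event cleaning

Defaults follow standard practice for reading event reports: a ±300 ms
interest period (straddling fixations are clipped and their durations
recomputed), removal of fixations immediately before/after or overlapping
a blink, fixation merging at 1°, a 50 ms minimum fixation duration, a
display-bounds filter, and a 0.5° minimum saccade amplitude. Rule order is
trim → blink-adjacent removal → merge → duration filter → bounds filter →
saccade derivation; merging precedes the duration filter so split fixation
fragments can survive as one merged fixation.

Two operational choices the generic rules leave open:

* **Merging is fragment-conditioned.** A consecutive pair within 1° merges
  only when at least one member is shorter than `merge_max_dur_ms`
  (default 100 ms). At this geometry 1° spans ~3 characters, so an
  unconditional merge would collapse ordinary fixations on adjacent short
  words and bias duration medians upward by ~35%; conditioning on a brief
  fragment restricts the rule to its purpose (re-gluing split fixations)
  while leaving genuine consecutive reading fixations intact. Merging is
  pairwise-sequential left-to-right and chain-absorbing within one pass.
* **Blink adjacency is temporal.** "Immediately before/after a blink"
  means no intervening fixation *and* a gap of at most
  `blink_adjacency_ms` (default 50 ms); this makes cleaning idempotent
  (a second pass removes nothing).

Every removal is counted per rule in a `CleaningReport`, and input counts
always equal retained + removed.

## Interest areas and assignment

Each word box is padded by 5 px on all sides; residual horizontal gaps
between neighbours on a line are split at the midpoint so each line is
tiled without gaps, and the vertical extent of a line's areas is unified
to the line's padded union (a geometric replacement for renderer-specific
gap-filling heuristics). A shared boundary belongs to the left/upper area.
Optional vertical drift correction searches integer pixel shifts within
± half the line spacing and applies, uniformly to all fixations of a
trial, the shift maximizing the number of in-area fixations (ties broken
by total distance to the nearest line center, then by smallest shift);
horizontal positions and individual fixations are never moved. It is off
by default — it operationalizes a manual inspect-and-shift step as a
reproducible optimizer.

## First-pass segmentation

An advancing frontier (highest word index fixated so far) partitions
fixations: a word's *first run* is the maximal consecutive block of
fixations delivered when the frontier first lands on it; words the
frontier jumps over without a prior fixation are *skipped during first
pass* (a later revisit does not un-skip them); everything behind the
frontier is a revisit. First-run dwell time, skip ratio, visited-words
ratio and fixations-per-word derive from this segmentation. The
fixations-per-word denominator is all words of the text, keeping the
metric independent of the visited-words ratio (config-switchable).
Unassigned fixations count toward duration statistics but not toward
word-based metrics. Reading duration (and words per minute) uses the full
untrimmed trial duration, since reading speed is a behavioral quantity
measured before event cleaning.

## Saccade taxonomy

Angles use `atan2(−Δy, Δx)` in (−180°, 180°], 0° = rightward reading
direction, positive = upward. Precedence: blink-adjacent > return-sweep >
undersweep > directional deviation > regression > forward > other.

* Return-sweep: launched within the last 3 words of a line, landing within
  the first 3 words of the next.
* Undersweep: launched within the last 4 words, landing on the next line
  beyond its first 3 words, *and* followed by a leftward corrective within
  that line. The corrective clause disambiguates undersweeps from accurate
  sweeps; the corrective saccade itself is classified as its own event
  ("other"), not as a regression — it lands on text not yet read, and the
  line-initial definition already treats "undersweep corrective saccade"
  as a distinct entity.
* Directional deviation: |angle| ∈ [35°, 145°] (inclusive bounds,
  configurable) and none of the above exclusions fired, including no blink
  immediately before, during or after the saccade (with re-derived
  saccades, equivalently a blink inside the inter-fixation span).
* Regression: landing on an earlier word previously visited or skipped.
* Line-initial fixation: per line, the temporally first fixation on one of
  the first two words, unless the next saccade stays on the line and lands
  left of it; at most one per line.

The deviation polar histogram uses 2.75°-wide bins tiling the two
qualifying bands [35°, 145°] and [−145°, −35°] exactly (40 bins each; a
2.75° width does not tile the full circle evenly), so bin counts sum to
the number of deviations.

## Scanpath similarity and clustering

Scasim dissimilarity is a global sequence alignment over fixations:
deleting/inserting a fixation costs its duration; substituting fixation
*a* for *b* costs `(d_a + d_b) − 2·min(d_a, d_b)·γ^dist`, with `dist` the
angular distance between positions in degrees and γ = 0.83 per degree
(both configurable; the modulator follows the metric's standard
parameterization). The dynamic program is JIT-compiled (numba) with a pure
NumPy substitution matrix. Scores are computed per text-font pair (the
metric is coordinate-based, and fonts shift word positions) and normalized
by the summed total fixation duration of the two trials, yielding a
fraction of viewing time spent dissimilarly; alternatives (mean, max)
exist in config, the sum was chosen because it bounds the raw score into
[0, 1].

Clustering mirrors a dist → isoMDS → mclustBIC → kmeans sequencing: the
score matrix is re-distanced (Euclidean distances between its rows — a
faithful-but-odd double distancing, with a direct option), embedded in 2-D
by non-metric MDS, the component count k is chosen by the best BIC over
Gaussian mixtures with k = 1…9, and k-means (50 restarts, fixed seed)
assigns trials. On tightly separated groups the BIC occasionally splits a
group into sub-clusters; association with group membership is therefore
tested on the k×2 contingency table — Pearson χ² when every expected count
exceeds 5, otherwise an exact Freeman–Halton test (margin-conditioned
enumeration; reduces to Fisher's exact test for 2×2). The strict
">5" branch boundary makes the balanced 10+10 pure-cluster case exact.

## Group statistics

Hedges' g = J·(m₁−m₂)/s_pooled with J = 1 − 3/(4·df − 1); group 1 is the
control group, so metrics on which the dyslexia group is larger carry a
negative sign. The exact analytical 95% CI inverts the noncentral-*t* CDF
for the noncentrality parameter at the 2.5%/97.5% points (bisection to
1e-8) and rescales by √(1/n₁+1/n₂); the endpoints carry no additional J
shrink, matching the convention of the exact-CI method's reference
implementation. A far-tail NaN in scipy's noncentral-*t* CDF is saturated
to 0/1 before root bracketing. The JZS Bayes factor integrates the
Cauchy-prior (width 0.7) marginal likelihood by adaptive quadrature split
at the prior mode and likelihood peak; percentage-bend correlation follows
the standard 20%-bend estimator (median-anchored bend scale ω, one-step
location estimate, ψ-clipped scores, t-distributed test statistic). The
GLMM layer builds the deviation-coded (−½/+½, then mean-centred) design
for group, font and their interaction with the maximal random-effects
descriptor (by-participant font slopes; by-text group/font/interaction
slopes; no random correlations) and performs likelihood-ratio χ²
comparisons from supplied deviances; the mixed-model solver itself is an
adapter seam, since the scientific content here is the design and the
comparison, not the optimizer.

## Synthetic cohorts

The generator is the package's test bed: it emulates the study conditions
(two groups × 9 texts × 2 fonts, ~150-word texts at ~84 characters per
line) with group profiles parameterized directly by the reported group
medians — fixation-duration medians 202 vs 224 ms (lognormal, σ = 0.32 on
the log scale; the median parameterization matches how such data are
reported), line-initial inflation +14 vs +32 ms (reproducing line-initial
medians 216 vs 256 ms), deviation rates 0.441 vs 1.003 per trial with
downward excursions for the dyslexia profile and upward for the control
profile, and equal regression hazard 0.06 per saccade. Where the source
conditions state no value, parameters were fixed once at field-typical
values: skip probability 0.25 vs 0.10 and refixation probability 0.15 vs
0.35 (producing the shorter-saccade/fewer-skips profile and reading rates
near 250 vs 160 wpm), undersweep probability 0.10 vs 0.20 per line break,
1.2 blinks per trial, 6 px landing noise. Word lengths are
1 + Poisson(λ=4) characters.

Generator mechanics worth knowing when interpreting tests:

* Saccades take a fixed 25 ms between fixations (event invariants require
  positive saccade durations; instantaneous saccades would violate them).
* Directional deviations are inserted as excursion–return pairs between
  two already-planned forward fixations at least 60 px apart. The
  excursion jumps down-left (or up-left) by a calibrated 35–50 px so its
  angle falls well inside the 35–145° band, lands mostly between text
  lines, and the return to the next planned fixation stays below 35° —
  each insertion therefore yields exactly one detectable deviation, and
  Monte-Carlo recovery of the insertion rate through the full
  clean/assign/classify chain is unbiased to within blink-exclusion losses
  (~2%).
* Regressions are single-fixation same-line revisits inserted with a
  per-slot rate rescaled by the trial's share of eligible transitions so
  that E[regressions/saccades] equals the profile hazard regardless of
  walk composition — two profiles with equal hazard produce matched
  regression *probabilities* while the profile with more saccades
  accumulates more regressions, the pattern the analysis is designed to
  distinguish.
* Refixations jump to the other side of the current word (≥ 18 px,
  confined to the word box, nearly horizontal), so they are recorded
  saccades, never vertical-deviation look-alikes, and never spill into
  neighbouring interest areas; words too short to host such a jump are not
  refixated.
* Per-trial seeds derive from `SeedSequence(master_seed, group,
  participant, text, font)`, so any subset of a cohort re-simulates
  identically.

What the generator does **not** emulate: linguistic content and
word-frequency/predictability effects, saccade dynamics (velocity
profiles, main sequence), binocular disparity, pupil signals, calibration
drift (drift is only injected explicitly in tests), or between-participant
heterogeneity beyond seed noise (all readers of a group share one
profile). Passing pipeline tests on this generator therefore validates the
measurement chain — event cleaning, geometry, segmentation, taxonomy,
alignment and statistics — not claims about real readers.

## Problem sizes and numerics

The profiled cohort runs use 10 participants per group × 9 texts × 2
fonts (360 trials, 18 text-font similarity analyses), a size chosen so the
full pipeline completes in well under a minute while leaving every
profiled effect strongly powered; statistical calibration checks use
2000–5000 Monte-Carlo replicates. Determinism: one integer seed drives
cohort simulation, MDS/GMM/k-means initialization and every Monte-Carlo
loop; re-running the pipeline with the same seed reproduces artifact
checksums bit-for-bit.

## Known limitations

* The Scasim normalization denominator and modulator of the original
  analyses are not published; numeric equality with any particular study's
  similarity matrices is not claimed, only the qualitative structure
  (between-group dissimilarity, cluster-group association).
* The exact Freeman–Halton enumeration is exponential in the cluster
  count and intended for the small tables (k ≤ ~6, n ≤ ~100) this design
  produces.
* `fixations_per_word` over all words and the inclusive 35°/145° band
  bounds are documented choices where the underlying definitions are
  ambiguous; both are configurable.
* Participant-level inference (e.g. proportion-consistent readers) takes
  precomputed participant means; the package does not model within-
  participant correlation beyond the GLMM design descriptor.
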