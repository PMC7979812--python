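"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the rule definitions with
different algorithms and data flow than the package code: exhaustive
alignment enumeration instead of dynamic programming, per-word set logic
instead of a frontier walk, and a flat boolean rule table instead of the
classifier's structured branching.
"""

from __future__ import annotations

import math

import numpy as np

from readscan.event_io import px_to_deg


# ---------------------------------------------------------------------------
# scanpath alignment by exhaustive enumeration
# ---------------------------------------------------------------------------

def scasim_enumerate(a, b, modulator, geometry) -> float:
    """Minimal alignment cost by recursive enumeration of all alignments."""
    a = [tuple(map(float, f)) for f in a]
    b = [tuple(map(float, f)) for f in b]

    def sub_cost(fa, fb):
        d = px_to_deg(math.hypot(fa[0] - fb[0], fa[1] - fb[1]), geometry)
        return fa[2] + fb[2] - 2.0 * min(fa[2], fb[2]) * modulator ** d

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = math.inf
        if i < len(a):
            best = min(best, a[i][2] + rec(i + 1, j))
        if j < len(b):
            best = min(best, b[j][2] + rec(i, j + 1))
        if i < len(a) and j < len(b):
            best = min(best, sub_cost(a[i], b[j]) + rec(i + 1, j + 1))
        return best

    return rec(0, 0)


# ---------------------------------------------------------------------------
# saccade-classification rule table
# ---------------------------------------------------------------------------

def brute_classify(trial, assigned, layout, cfg) -> list[str]:
    """Re-evaluate every classification rule as a flat boolean table."""
    words = [a.word_index for a in assigned]
    lines = [a.line_index for a in assigned]
    cats = []
    for n, s in enumerate(trial.saccades):
        dx, dy = s.x1 - s.x0, s.y1 - s.y0
        if dx == 0 and dy == 0:
            cats.append("other")
            continue
        angle = math.degrees(math.atan2(-dy, dx))
        if angle == -180.0:
            angle = 180.0
        wj, wk = words[s.from_fix], words[s.to_fix]
        lj, lk = lines[s.from_fix], lines[s.to_fix]

        blink = any(b.onset < s.offset and b.offset > s.onset
                    for b in trial.blinks)

        sweepish = (wj is not None and wk is not None and lk == lj + 1)
        if sweepish:
            _, from_end = layout.within_line_position(wj)
            from_start, _ = layout.within_line_position(wk)
        is_sweep = sweepish and from_end <= 2 and from_start <= 2
        is_under = False
        if sweepish and from_end <= 3 and from_start >= 3:
            follow = [t for t in trial.saccades if t.from_fix == s.to_fix]
            if follow:
                t = follow[0]
                is_under = (lines[t.to_fix] == lk and t.x1 < t.x0)

        lo, hi = cfg.deviation_min_deg, cfg.deviation_max_deg
        in_band = (lo <= abs(angle) <= hi if cfg.inclusive_bounds
                   else lo < abs(angle) < hi)

        # corrective saccade completing the undersweep labelled just before
        prev = [m for m, t in enumerate(trial.saccades)
                if t.to_fix == s.from_fix]
        is_corrective = (dx < 0 and lj == lk and bool(prev)
                         and cats[prev[0]] == "undersweep")

        visited_or_skipped = False
        if wj is not None and wk is not None and wk < wj:
            earlier = [w for a in assigned[:s.to_fix]
                       if (w := a.word_index) is not None]
            visited_or_skipped = bool(earlier) and wk <= max(earlier)

        if blink:
            cats.append("blink_adjacent")
        elif is_sweep:
            cats.append("return_sweep")
        elif is_under:
            cats.append("undersweep")
        elif in_band:
            cats.append("directional_deviation")
        elif is_corrective:
            cats.append("other")
        elif visited_or_skipped:
            cats.append("regression")
        elif abs(angle) < lo:
            cats.append("forward")
        else:
            cats.append("other")
    return cats


# ---------------------------------------------------------------------------
# reading metrics recomputed from scratch
# ---------------------------------------------------------------------------

def brute_metrics(trial, assigned, layout, categories) -> dict:
    """Recompute every trial metric with per-word set logic and numpy."""
    words = [a.word_index for a in assigned]
    n_words = layout.n_words

    first_fix_on = {}
    for i, w in enumerate(words):
        if w is not None and w not in first_fix_on:
            first_fix_on[w] = i

    def frontier_before(i):
        prior = [w for w in words[:i] if w is not None]
        return max(prior) if prior else -1

    first_runs = {}
    for w, i in first_fix_on.items():
        if frontier_before(i) < w:
            run = [i]
            for j in range(i + 1, len(words)):
                if words[j] == w:
                    run.append(j)
                else:
                    break
            first_runs[w] = run
    visited = {w for w in words if w is not None}
    fixated_words_sorted = sorted(visited)
    skipped = set()
    for w in range(n_words):
        if w in first_runs:
            continue
        later = [v for v in visited if v > w]
        if not later:
            continue
        first_beyond = min(first_fix_on[v] for v in later)
        if w not in visited or first_fix_on[w] > first_beyond:
            skipped.add(w)

    durs = np.array([f.duration for f in trial.fixations])
    amps = np.array([s.amplitude_deg for s in trial.saccades])
    cats = np.array(categories)
    n_reg = int(np.sum(cats == "regression"))

    dwell = sum(trial.fixations[i].duration
                for run in first_runs.values() for i in run)
    out = {
        "mean_fixdur": float(durs.mean()),
        "median_fixdur": float(np.median(durs)),
        "total_scanpath": float(amps.sum()),
        "mean_sacc_amp": float(amps.mean()),
        "median_sacc_amp": float(np.median(amps)),
        "sd_sacc_amp": float(amps.std(ddof=1)),
        "first_run_dwell_time": dwell / 1000.0,
        "ratio_first_run_words_skipped": len(skipped) / n_words,
        "ratio_visited_words": len(visited) / n_words,
        "fixations_per_word":
            sum(1 for w in words if w is not None) / n_words,
        "n_regressions": n_reg,
        "regression_probability": n_reg / len(amps) if len(amps) else 0.0,
        "n_directional_deviations":
            int(np.sum(cats == "directional_deviation")),
        "reading_duration": trial.trial_duration / 1000.0,
        "wpm": n_words / (trial.trial_duration / 60000.0),
    }
    return out
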