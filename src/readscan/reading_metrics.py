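"""Global (trial-level) and local (word-level) reading metrics.

First-pass segmentation follows the advancing-frontier rule: the frontier
is the highest word index fixated so far; fixations on words behind it are
revisits, words the frontier jumps over without a prior fixation are
skipped during first pass, and a word's first run is the maximal block of
consecutive fixations delivered when the frontier first lands on it.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .event_io import TrialRecord
from .interest_mapping import AssignedFixation
from .layout import TextLayout
from .saccade_taxonomy import (LineInitialFixation, SaccadeLabel,
                               TaxonomyConfig, classify_saccades,
                               detect_line_initial)


@dataclass
class FirstPassSegmentation:
    n_words: int
    first_run: dict[int, list[int]]      # word -> fixation indices
    skipped_first_pass: set[int]
    visited_ever: set[int]
    n_fixations_per_word: dict[int, int]
    empty: bool = False                  # no assigned fixations at all


def segment_first_pass(
    assigned: Sequence[AssignedFixation], n_words: int,
) -> FirstPassSegmentation:
    first_run: dict[int, list[int]] = {}
    skipped: set[int] = set()
    visited: set[int] = set()
    counts: dict[int, int] = {}
    frontier = -1
    run_word: int | None = None
    for i, a in enumerate(assigned):
        w = a.word_index
        if w is None:
            run_word = None
            continue
        visited.add(w)
        counts[w] = counts.get(w, 0) + 1
        if w > frontier:
            for s in range(frontier + 1, w):
                if s not in visited:
                    skipped.add(s)
            frontier = w
            first_run[w] = [i]
            run_word = w
        elif w == run_word:
            first_run[w].append(i)
        else:
            run_word = None
    return FirstPassSegmentation(
        n_words=n_words, first_run=first_run, skipped_first_pass=skipped,
        visited_ever=visited, n_fixations_per_word=counts,
        empty=not visited,
    )


@dataclass
class TrialMetrics:
    """The per-trial vector of reading metrics (the unit of every group
    comparison).  Durations in ms unless stated; dwell and reading duration
    in seconds; amplitudes and scanpath in degrees of visual angle."""

    mean_fixdur: float = math.nan
    median_fixdur: float = math.nan
    total_scanpath: float = math.nan
    mean_sacc_amp: float = math.nan
    median_sacc_amp: float = math.nan
    sd_sacc_amp: float = math.nan
    first_run_dwell_time: float = math.nan
    ratio_first_run_words_skipped: float = math.nan
    ratio_visited_words: float = math.nan
    fixations_per_word: float = math.nan
    n_regressions: int = 0
    regression_probability: float = 0.0
    reading_duration: float = math.nan
    wpm: float = math.nan
    median_line_initial_fixdur: float = math.nan
    n_directional_deviations: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


METRIC_COLUMNS = list(TrialMetrics().to_dict().keys())


def compute_local_metrics(
    segmentation: FirstPassSegmentation,
    assigned: Sequence[AssignedFixation],
) -> dict[str, float]:
    """Word-based metrics from the first-pass segmentation.

    The fixations-per-word denominator is the full word count of the text
    (all words, visited or not), keeping it independent of the visited-words
    ratio.
    """
    n_words = segmentation.n_words
    dwell_ms = sum(
        assigned[i].fixation.duration
        for run in segmentation.first_run.values() for i in run
    )
    n_assigned = sum(segmentation.n_fixations_per_word.values())
    return {
        "first_run_dwell_time": dwell_ms / 1000.0,
        "ratio_first_run_words_skipped":
            len(segmentation.skipped_first_pass) / n_words,
        "ratio_visited_words": len(segmentation.visited_ever) / n_words,
        "fixations_per_word": n_assigned / n_words,
    }


def compute_global_metrics(
    trial: TrialRecord, labels: Sequence[SaccadeLabel],
) -> dict[str, float]:
    """Trial-level central tendencies and regression counts."""
    out: dict[str, float] = {}
    durs = [f.duration for f in trial.fixations]
    if durs:
        out["mean_fixdur"] = statistics.fmean(durs)
        out["median_fixdur"] = statistics.median(durs)
    amps = [s.amplitude_deg for s in trial.saccades]
    n_sacc = len(amps)
    if n_sacc:
        out["total_scanpath"] = float(sum(amps))
        out["mean_sacc_amp"] = statistics.fmean(amps)
        out["median_sacc_amp"] = statistics.median(amps)
        out["sd_sacc_amp"] = (statistics.stdev(amps) if n_sacc > 1
                              else 0.0)
    n_reg = sum(1 for lb in labels if lb.category == "regression")
    out["n_regressions"] = n_reg
    out["regression_probability"] = n_reg / n_sacc if n_sacc else 0.0
    out["n_directional_deviations"] = sum(
        1 for lb in labels if lb.category == "directional_deviation")
    return out


def reading_speed_wpm(trial: TrialRecord, layout: TextLayout) -> float:
    """Words per minute over the full (untrimmed) trial duration."""
    if trial.trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    minutes = trial.trial_duration / 60000.0
    return layout.n_words / minutes


def trial_metrics(
    trial: TrialRecord,
    assigned: Sequence[AssignedFixation],
    layout: TextLayout,
    taxonomy: TaxonomyConfig | None = None,
    labels: Sequence[SaccadeLabel] | None = None,
) -> TrialMetrics:
    """All metrics for one cleaned, word-assigned trial."""
    if labels is None:
        labels = classify_saccades(trial, assigned, layout, taxonomy)
    seg = segment_first_pass(assigned, layout.n_words)
    values = {}
    values.update(compute_global_metrics(trial, labels))
    values.update(compute_local_metrics(seg, assigned))
    values["reading_duration"] = trial.trial_duration / 1000.0
    values["wpm"] = reading_speed_wpm(trial, layout)
    line_initial = detect_line_initial(trial, assigned, layout)
    if line_initial:
        values["median_line_initial_fixdur"] = statistics.median(
            [li.duration for li in line_initial])
    return TrialMetrics(**values)


def normalize_profile(
    metrics: pd.DataFrame,
    metric_columns: Sequence[str],
    group_column: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Z-score each metric across all trials of both groups, then average
    per group.  Returns (z-scored table, group means, excluded columns);
    zero-variance metrics are flagged and excluded.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 trials to z-score")
    z = metrics.copy()
    excluded: list[str] = []
    kept: list[str] = []
    for col in metric_columns:
        values = metrics[col].astype(float)
        sd = values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            excluded.append(col)
            z = z.drop(columns=[col])
            continue
        z[col] = (values - values.mean()) / sd
        kept.append(col)
    group_means = z.groupby(group_column)[kept].mean()
    return z, group_means, excluded
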