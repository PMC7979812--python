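"""Event cleaning: interest period, blink handling, merging, filtering.

Rule order (configurable only through the individual functions; the
:func:`clean_trial` driver applies the full sequence):

1. interest period — drop events wholly inside the first/last 300 ms,
   clip fixations straddling a boundary;
2. blink-adjacent removal — drop fixations immediately before/after a blink
   (temporal adjacency within ``blink_adjacency_ms``, no intervening
   fixation) and fixations overlapping a blink;
3. merging — consecutive fixations closer than the merging amplitude (1 deg)
   are merged pairwise left-to-right, position duration-weighted, unless a
   blink intervenes; merging only engages when one member of the pair is a
   brief fragment (under ``merge_max_dur_ms``), mirroring the intent of a
   merging-amplitude parameter: glue split fixation fragments back together
   without collapsing ordinary consecutive reading fixations on short words;
4. minimum duration — fixations shorter than 50 ms are dropped;
5. display bounds — fixations beyond the screen are dropped;
6. saccade derivation — saccades are regenerated between consecutive
   retained fixations; displacements under the minimum saccade amplitude
   (0.5 deg) produce no saccade; a saccade spanning a blink is flagged.

Merging precedes the duration filter so short refixation fragments can
survive as one merged fixation.  Every removal is counted in the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .event_io import (BlinkEvent, DisplayGeometry, FixationEvent,
                       SaccadeEvent, TrialRecord, px_to_deg)


@dataclass(frozen=True)
class CleaningConfig:
    interest_trim_ms: float = 300.0
    min_fix_ms: float = 50.0
    merge_amp_deg: float = 1.0
    min_sacc_amp_deg: float = 0.5
    drop_blink_adjacent: bool = True
    enforce_bounds: bool = True
    blink_adjacency_ms: float = 50.0
    merge_max_dur_ms: float = 100.0  # only pairs with a member this brief merge

    def __post_init__(self) -> None:
        for name in ("interest_trim_ms", "min_fix_ms", "merge_amp_deg",
                     "min_sacc_amp_deg", "blink_adjacency_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CleaningReport:
    """Per-trial accounting of what each rule did."""

    n_input_fixations: int = 0
    n_trimmed: int = 0          # events wholly outside the interest period
    n_clipped: int = 0          # fixations clipped at a boundary (retained)
    n_blink_adjacent: int = 0
    n_merged_away: int = 0      # fixations absorbed into a merge partner
    n_short: int = 0
    n_out_of_bounds: int = 0
    n_retained: int = 0
    trial_excluded: bool = False
    reason: str = ""

    def conserves(self) -> bool:
        removed = (self.n_trimmed + self.n_blink_adjacent + self.n_merged_away
                   + self.n_short + self.n_out_of_bounds)
        return self.n_input_fixations == removed + self.n_retained


def apply_interest_period(
    trial: TrialRecord, config: CleaningConfig | None = None,
    report: CleaningReport | None = None,
) -> TrialRecord:
    """Restrict events to [trim, T - trim]; clip straddling fixations."""
    config = config or CleaningConfig()
    trim = config.interest_trim_ms
    lo, hi = trim, trial.trial_duration - trim
    if hi <= lo:
        out = replace_events(trial, [], [], [])
        out.excluded = True
        out.exclusion_reason = "trial shorter than twice the interest trim"
        if report is not None:
            report.trial_excluded = True
            report.reason = out.exclusion_reason
            report.n_trimmed += len(trial.fixations)
        return out

    fixations: list[FixationEvent] = []
    for f in trial.fixations:
        if f.offset <= lo or f.onset >= hi:
            if report is not None:
                report.n_trimmed += 1
            continue
        onset, offset = max(f.onset, lo), min(f.offset, hi)
        if (onset, offset) != (f.onset, f.offset):
            if report is not None:
                report.n_clipped += 1
            f = FixationEvent(onset, offset, f.x, f.y)
        fixations.append(f)
    blinks = [b for b in trial.blinks if b.offset > lo and b.onset < hi]
    saccades = [s for s in trial.saccades if s.offset > lo and s.onset < hi]
    out = replace_events(trial, fixations, saccades, blinks)
    if not fixations:
        out.excluded = True
        out.exclusion_reason = "no events inside the interest period"
        if report is not None:
            report.trial_excluded = True
            report.reason = out.exclusion_reason
    return out


def _remove_blink_adjacent(
    fixations: list[FixationEvent], blinks: list[BlinkEvent],
    adjacency_ms: float,
) -> tuple[list[FixationEvent], int]:
    doomed: set[int] = set()
    for b in blinks:
        before = [i for i, f in enumerate(fixations) if f.offset <= b.onset]
        if before:
            i = before[-1]
            if b.onset - fixations[i].offset <= adjacency_ms:
                doomed.add(i)
        after = [i for i, f in enumerate(fixations) if f.onset >= b.offset]
        if after:
            i = after[0]
            if fixations[i].onset - b.offset <= adjacency_ms:
                doomed.add(i)
        for i, f in enumerate(fixations):  # overlap (rare, malformed streams)
            if f.onset < b.offset and f.offset > b.onset:
                doomed.add(i)
    kept = [f for i, f in enumerate(fixations) if i not in doomed]
    return kept, len(doomed)


def merge_and_filter_fixations(
    trial: TrialRecord,
    config: CleaningConfig | None = None,
    report: CleaningReport | None = None,
) -> tuple[TrialRecord, CleaningReport]:
    """Blink-adjacent removal, pairwise merging, duration and bounds filters."""
    config = config or CleaningConfig()
    geometry = trial.geometry
    if report is None:
        report = CleaningReport(n_input_fixations=len(trial.fixations))

    fixations = list(trial.fixations)
    if config.drop_blink_adjacent and trial.blinks:
        fixations, n = _remove_blink_adjacent(
            fixations, trial.blinks, config.blink_adjacency_ms)
        report.n_blink_adjacent += n

    # pairwise sequential left-to-right merging
    def blink_between(a: FixationEvent, b: FixationEvent) -> bool:
        return any(bl.onset >= a.offset and bl.offset <= b.onset
                   for bl in trial.blinks)

    merged: list[FixationEvent] = []
    for f in fixations:
        if merged:
            prev = merged[-1]
            dist_deg = px_to_deg(math.hypot(f.x - prev.x, f.y - prev.y),
                                 geometry)
            fragment = (prev.duration < config.merge_max_dur_ms
                        or f.duration < config.merge_max_dur_ms)
            if (dist_deg < config.merge_amp_deg and fragment
                    and not blink_between(prev, f)):
                d1, d2 = prev.duration, f.duration
                w = d1 + d2
                merged[-1] = FixationEvent(
                    prev.onset, f.offset,
                    (prev.x * d1 + f.x * d2) / w,
                    (prev.y * d1 + f.y * d2) / w,
                )
                report.n_merged_away += 1
                continue
        merged.append(f)

    kept: list[FixationEvent] = []
    for f in merged:
        if f.duration < config.min_fix_ms:
            report.n_short += 1
            continue
        if config.enforce_bounds and not (
                0 <= f.x <= geometry.width_px and 0 <= f.y <= geometry.height_px):
            report.n_out_of_bounds += 1
            continue
        kept.append(f)

    report.n_retained = len(kept)
    out = replace_events(trial, kept, [], list(trial.blinks))
    return out, report


def derive_saccades(
    trial: TrialRecord, config: CleaningConfig | None = None,
) -> TrialRecord:
    """Regenerate saccades between consecutive retained fixations.

    Start point/time is the earlier fixation's position/offset, end the
    later fixation's position/onset.  Displacements below the minimum
    amplitude yield no record.  A blink anywhere inside the inter-fixation
    span sets the blink flag.
    """
    config = config or CleaningConfig()
    geometry = trial.geometry
    saccades: list[SaccadeEvent] = []
    for i in range(len(trial.fixations) - 1):
        a, b = trial.fixations[i], trial.fixations[i + 1]
        amp = px_to_deg(math.hypot(b.x - a.x, b.y - a.y), geometry)
        if amp < config.min_sacc_amp_deg:
            continue
        onset = a.offset
        offset = max(b.onset, onset + 1e-3)
        blink = any(bl.onset < offset and bl.offset > onset
                    for bl in trial.blinks)
        saccades.append(SaccadeEvent(
            onset, offset, a.x, a.y, b.x, b.y,
            amplitude_deg=amp, blink_flagged=blink,
            from_fix=i, to_fix=i + 1,
        ))
    return replace_events(trial, list(trial.fixations), saccades,
                          list(trial.blinks))


def clean_trial(
    trial: TrialRecord, config: CleaningConfig | None = None,
) -> tuple[TrialRecord, CleaningReport]:
    """Full cleaning sequence: trim, blink rules, merge, filter, saccades."""
    config = config or CleaningConfig()
    report = CleaningReport(n_input_fixations=len(trial.fixations))
    t = apply_interest_period(trial, config, report)
    if t.excluded:
        report.n_retained = 0
        return t, report
    t, report = merge_and_filter_fixations(t, config, report)
    t = derive_saccades(t, config)
    return t, report


def replace_events(trial: TrialRecord, fixations, saccades, blinks) -> TrialRecord:
    return TrialRecord(
        participant_id=trial.participant_id, group=trial.group,
        font=trial.font, text_id=trial.text_id,
        fixations=fixations, saccades=saccades, blinks=blinks,
        geometry=trial.geometry, trial_duration=trial.trial_duration,
        excluded=trial.excluded, exclusion_reason=trial.exclusion_reason,
    )
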