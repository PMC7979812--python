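"""Word-based interest areas, fixation-to-word assignment, drift correction.

Each word box is padded by 5 px on all sides; residual horizontal gaps
between neighbouring words on a line are split at the midpoint so every
line is fully tiled, and the vertical extent of a line's areas is unified
to the line's padded union.  A boundary shared by two areas belongs to the
left (respectively upper) one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .event_io import FixationEvent, TrialRecord
from .layout import TextLayout
from .preprocess import replace_events


@dataclass(frozen=True)
class InterestArea:
    word_index: int
    line_index: int
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class AssignedFixation:
    fixation: FixationEvent
    word_index: int | None
    line_index: int | None

    @property
    def in_ia(self) -> bool:
        return self.word_index is not None


def build_interest_areas(
    layout: TextLayout, padding_px: float = 5.0,
) -> list[InterestArea]:
    """Pad word boxes, close within-line gaps, unify line heights."""
    if padding_px < 0:
        raise ValueError("padding_px must be >= 0")
    areas: list[InterestArea] = []
    for line in range(layout.line_count):
        words = layout.words_on_line(line)
        y0 = min(w.y0 for w in words) - padding_px
        y1 = max(w.y1 for w in words) + padding_px
        edges: list[tuple[float, float]] = []
        for w in words:
            edges.append((w.x0 - padding_px, w.x1 + padding_px))
        # split residual gaps / padding overlaps at the midpoint
        for i in range(len(edges) - 1):
            left, right = edges[i], edges[i + 1]
            if left[1] != right[0]:
                mid = 0.5 * (left[1] + right[0])
                edges[i] = (left[0], mid)
                edges[i + 1] = (mid, right[1])
        for w, (x0, x1) in zip(words, edges):
            if x1 <= x0:
                raise ValueError(
                    f"word {w.word_index}: interest area collapsed "
                    "(overlapping word boxes in layout)")
            areas.append(InterestArea(w.word_index, line, x0, y0, x1, y1))
    return areas


def _area_lookup(areas: Sequence[InterestArea]):
    by_line: dict[int, list[InterestArea]] = {}
    for a in areas:
        by_line.setdefault(a.line_index, []).append(a)
    rows = []
    for line in sorted(by_line):
        row = sorted(by_line[line], key=lambda a: a.x0)
        rows.append((row[0].y0, row[0].y1, row))
    return rows


def assign_fixations(
    trial: TrialRecord, areas: Sequence[InterestArea],
) -> list[AssignedFixation]:
    """Point-in-rectangle assignment; ties resolved left/upper by scan order."""
    rows = _area_lookup(areas)
    out: list[AssignedFixation] = []
    for f in trial.fixations:
        word = line = None
        for y0, y1, row in rows:
            if y0 <= f.y <= y1:
                for a in row:
                    if a.x0 <= f.x <= a.x1:
                        word, line = a.word_index, a.line_index
                        break
                break
        out.append(AssignedFixation(f, word, line))
    return out


def correct_vertical_drift(
    trial: TrialRecord,
    areas: Sequence[InterestArea],
    mode: str = "global_shift",
    max_shift_px: int | None = None,
) -> tuple[TrialRecord, int]:
    """Uniform vertical shift maximizing the number of in-area fixations.

    Searches integer pixel shifts within +/- half the line spacing and
    applies the best one to every fixation of the trial; horizontal
    coordinates are never touched, and no fixation is moved individually.
    ``mode="off"`` returns the trial unchanged.
    """
    if mode == "off":
        return trial, 0
    if mode != "global_shift":
        raise ValueError(f"unknown drift mode {mode!r}")
    rows = _area_lookup(areas)
    if max_shift_px is None:
        if len(rows) >= 2:
            spacing = rows[1][0] - rows[0][0]
        else:
            spacing = rows[0][1] - rows[0][0]
        max_shift_px = max(1, int(spacing // 2))

    centers = [0.5 * (y0 + y1) for y0, y1, _ in rows]

    def objective(shift: float) -> tuple[int, float]:
        count, dist = 0, 0.0
        for f in trial.fixations:
            y = f.y + shift
            dist += min(abs(y - c) for c in centers)
            for y0, y1, row in rows:
                if y0 <= y <= y1:
                    if any(a.x0 <= f.x <= a.x1 for a in row):
                        count += 1
                    break
        return count, dist

    # maximize in-area count; break count ties by total distance to the
    # nearest line center (so plateaus resolve to the centred shift), then
    # by the smallest magnitude of correction
    shifts = sorted(range(-max_shift_px, max_shift_px + 1),
                    key=lambda s: (abs(s), s))
    best_shift, best_count, best_dist = 0, -1, math.inf
    for s in shifts:
        c, d = objective(s)
        if c > best_count or (c == best_count and d < best_dist - 1e-9):
            best_shift, best_count, best_dist = s, c, d
    if best_shift == 0:
        return trial, 0
    shifted = [FixationEvent(f.onset, f.offset, f.x, f.y + best_shift)
               for f in trial.fixations]
    return replace_events(trial, shifted, list(trial.saccades),
                          list(trial.blinks)), best_shift
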