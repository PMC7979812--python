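"""Saccade classification and line-initial fixation detection.

Angle convention: 0 deg is the horizontal rightward reading direction,
positive angles point upward; because screen y grows downward the angle of
a displacement (dx, dy) is ``atan2(-dy, dx)`` in (-180, 180].

Categories (exactly one per saccade, in precedence order):

* ``blink_adjacent`` — a blink falls immediately before, during or after
  the saccade (no intervening fixation; with re-derived saccades this is
  equivalent to a blink inside the inter-fixation span);
* ``return_sweep`` — launched within the last 3 words of a line, landing
  within the first 3 words of the next line;
* ``undersweep`` — launched within the last 4 words of a line, landing on
  the next line beyond its first 3 words, followed by a leftward corrective
  saccade within that line;
* ``directional_deviation`` — |angle| within [35, 145] deg (inclusive,
  configurable), i.e. a jump steeply up or down, atypical for reading;
* ``regression`` — landing on an earlier word that was previously visited
  or skipped;
* ``forward`` — |angle| below the deviation band (rightward progression);
* ``other`` — anything left (e.g. long leftward saccades to unvisited text,
  zero displacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .event_io import SaccadeEvent, TrialRecord
from .interest_mapping import AssignedFixation
from .layout import TextLayout

CATEGORIES = ("forward", "regression", "return_sweep", "undersweep",
              "blink_adjacent", "directional_deviation", "other")


@dataclass(frozen=True)
class TaxonomyConfig:
    deviation_min_deg: float = 35.0
    deviation_max_deg: float = 145.0
    inclusive_bounds: bool = True
    sweep_launch_words: int = 3   # last N words of a line
    sweep_land_words: int = 3     # first N words of the next line
    undersweep_launch_words: int = 4


@dataclass(frozen=True)
class SaccadeLabel:
    saccade_index: int
    category: str
    angle: float
    launch_word: int | None
    landing_word: int | None


@dataclass(frozen=True)
class LineInitialFixation:
    fixation_index: int
    line_index: int
    duration: float


def saccade_angle(dx_px: float, dy_px: float) -> float:
    """Angle of a screen displacement in degrees, range (-180, 180]."""
    if dx_px == 0 and dy_px == 0:
        raise ValueError("zero displacement has no angle")
    a = math.degrees(math.atan2(-dy_px, dx_px))
    return 180.0 if a == -180.0 else a


def _in_deviation_band(angle: float, config: TaxonomyConfig) -> bool:
    m = abs(angle)
    if config.inclusive_bounds:
        return config.deviation_min_deg <= m <= config.deviation_max_deg
    return config.deviation_min_deg < m < config.deviation_max_deg


def classify_saccades(
    trial: TrialRecord,
    assigned: Sequence[AssignedFixation],
    layout: TextLayout,
    config: TaxonomyConfig | None = None,
) -> list[SaccadeLabel]:
    """Label every derived saccade of a cleaned, word-assigned trial."""
    config = config or TaxonomyConfig()
    labels: list[SaccadeLabel] = []

    words = [a.word_index for a in assigned]
    lines = [a.line_index for a in assigned]
    xs = [a.fixation.x for a in assigned]

    # running frontier: highest word index reached before fixation k
    frontier_before = []
    frontier = -1
    for w in words:
        frontier_before.append(frontier)
        if w is not None:
            frontier = max(frontier, w)

    sac_by_from = {s.from_fix: (i, s) for i, s in enumerate(trial.saccades)}

    for idx, s in enumerate(trial.saccades):
        dx, dy = s.x1 - s.x0, s.y1 - s.y0
        j, k = s.from_fix, s.to_fix
        w_j = words[j] if 0 <= j < len(words) else None
        w_k = words[k] if 0 <= k < len(words) else None
        l_j = lines[j] if 0 <= j < len(words) else None
        l_k = lines[k] if 0 <= k < len(words) else None
        if dx == 0 and dy == 0:
            labels.append(SaccadeLabel(idx, "other", float("nan"), w_j, w_k))
            continue
        angle = saccade_angle(dx, dy)

        category = None
        if s.blink_flagged:
            category = "blink_adjacent"
        elif (w_j is not None and w_k is not None
              and l_k == l_j + 1):
            from_end = layout.within_line_position(w_j)[1]
            from_start = layout.within_line_position(w_k)[0]
            if (from_end < config.sweep_launch_words
                    and from_start < config.sweep_land_words):
                category = "return_sweep"
            elif (from_end < config.undersweep_launch_words
                  and from_start >= config.sweep_land_words):
                nxt = sac_by_from.get(k)
                if nxt is not None:
                    _, ns = nxt
                    land_line = lines[ns.to_fix] if 0 <= ns.to_fix < len(words) else None
                    if land_line == l_k and ns.x1 < ns.x0:
                        category = "undersweep"
        if category is None and _in_deviation_band(angle, config):
            category = "directional_deviation"
        if category is None and labels and dx < 0 and l_j == l_k:
            # the leftward corrective completing an undersweep is its own
            # event, not a regression (it lands on text never yet read)
            prev = next((lb for lb in labels[::-1]
                         if trial.saccades[lb.saccade_index].to_fix == j), None)
            if prev is not None and prev.category == "undersweep":
                category = "other"
        if category is None:
            if (w_j is not None and w_k is not None and w_k < w_j
                    and w_k <= frontier_before[k]):
                category = "regression"
            elif abs(angle) < config.deviation_min_deg:
                category = "forward"
            else:
                category = "other"
        labels.append(SaccadeLabel(idx, category, angle, w_j, w_k))
    return labels


def detect_line_initial(
    trial: TrialRecord,
    assigned: Sequence[AssignedFixation],
    layout: TextLayout,
) -> list[LineInitialFixation]:
    """First fixation on one of a line's first two words, not followed by a
    leftward corrective saccade within the same line.  At most one per line.
    """
    sac_by_from = {s.from_fix: s for s in trial.saccades}
    lines_words = [(a.line_index, a.word_index) for a in assigned]
    seen_lines: set[int] = set()
    out: list[LineInitialFixation] = []
    for i, (line, word) in enumerate(lines_words):
        if word is None or line in seen_lines:
            continue
        if layout.within_line_position(word)[0] > 1:
            continue
        seen_lines.add(line)  # the candidate is unique per line, valid or not
        nxt = sac_by_from.get(i)
        if nxt is not None:
            land = nxt.to_fix
            land_line = assigned[land].line_index if 0 <= land < len(assigned) else None
            if land_line == line and nxt.x1 < assigned[i].fixation.x:
                continue  # leftward corrective within the line: disqualified
        out.append(LineInitialFixation(i, line, assigned[i].fixation.duration))
    return out


def polar_histogram(
    angles: Sequence[float],
    bin_width: float = 2.75,
    band: tuple[float, float] = (35.0, 145.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of directional-deviation angles in 2.75-deg bins.

    Bins tile the two qualifying half-bands [-145, -35] and [35, 145]
    (each an exact multiple of the bin width); every deviation angle falls
    in exactly one bin, so the counts sum to the number of deviations.
    Returns (edges, counts) where ``edges`` has one more entry than
    ``counts`` and the two bands are concatenated.
    """
    lo, hi = band
    n = int(round((hi - lo) / bin_width))
    if not math.isclose(lo + n * bin_width, hi):
        raise ValueError("band width must be a multiple of bin_width")
    neg_edges = np.linspace(-hi, -lo, n + 1)
    pos_edges = np.linspace(lo, hi, n + 1)
    a = np.asarray(angles, dtype=float)
    # numpy's histogram makes the final bin right-inclusive, so the band
    # endpoints -35 and 145 are kept
    neg_counts, _ = np.histogram(a[a < 0], bins=neg_edges)
    pos_counts, _ = np.histogram(a[a >= 0], bins=pos_edges)
    edges = np.concatenate([neg_edges, pos_edges])
    counts = np.concatenate([neg_counts, pos_counts])
    return edges, counts
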