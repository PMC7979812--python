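"""Per-trial eye-movement event streams and their tab-separated on-disk dialect.

The format is a neutral analogue of an EyeLink DataViewer event report:
UTF-8 TSV, one row per event, columns

    participant  group  font  text  trial  event_type  onset  offset  x0  y0  x1  y1

Timestamps are trial-relative milliseconds.  Coordinates are 0-based pixels,
origin top-left, y downward.  One extra ``trial`` row per trial carries the
full trial duration (space-bar to space-bar) so round-trips are lossless.
Only a single (selected) eye is represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

COLUMNS = [
    "participant", "group", "font", "text", "trial",
    "event_type", "onset", "offset", "x0", "y0", "x1", "y1",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display description used for pixel -> degree conversion.

    Defaults describe a 1024x768 CRT viewed at 70 cm with ~0.38 mm pixels.
    """

    width_px: float = 1024.0
    height_px: float = 768.0
    px_size_mm: float = 0.38
    viewing_distance_mm: float = 700.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "px_size_mm", "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def px_to_deg(distance_px, geometry: DisplayGeometry):
    """Convert an on-screen pixel distance to degrees of visual angle.

    Uses the full (non-small-angle) formula
    ``2 * atan(d_px * px_mm / (2 * viewing_distance_mm))``.
    Accepts scalars or arrays; monotone increasing in ``distance_px``.
    """
    d = np.asarray(distance_px, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_px must be non-negative")
    out = np.degrees(
        2.0 * np.arctan(d * geometry.px_size_mm / (2.0 * geometry.viewing_distance_mm))
    )
    return float(out) if np.isscalar(distance_px) else out


def deg_to_px(angle_deg: float, geometry: DisplayGeometry) -> float:
    """Inverse of :func:`px_to_deg` (scalar)."""
    if angle_deg < 0:
        raise ValueError("angle must be non-negative")
    return (
        2.0 * geometry.viewing_distance_mm
        * math.tan(math.radians(angle_deg) / 2.0) / geometry.px_size_mm
    )


@dataclass(frozen=True)
class FixationEvent:
    onset: float
    offset: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("fixation offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float
    offset: float
    x0: float
    y0: float
    x1: float
    y1: float
    amplitude_deg: float = float("nan")
    blink_flagged: bool = False
    # indices into the trial's fixation list; derived saccades carry these
    from_fix: int = -1
    to_fix: int = -1

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("saccade offset must exceed onset")
        if not math.isnan(self.amplitude_deg) and self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class BlinkEvent:
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("blink offset must exceed onset")


@dataclass
class TrialRecord:
    """One trial's ordered event streams plus identifying labels."""

    participant_id: str
    group: str            # "control" | "dyslexia"
    font: str             # e.g. "TNR" | "OpenDyslexic"
    text_id: str
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    blinks: list[BlinkEvent] = field(default_factory=list)
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    trial_duration: float = 0.0
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def trial_id(self) -> str:
        return f"{self.participant_id}|{self.text_id}|{self.font}"

    def validate(self) -> None:
        for events in (self.fixations, self.saccades, self.blinks):
            for a, b in zip(events, events[1:]):
                if b.onset < a.onset:
                    raise ValueError("events not time-ordered")
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.onset < a.offset:
                raise ValueError("overlapping fixations")
        last = max(
            (ev.offset for ev in (*self.fixations, *self.saccades, *self.blinks)),
            default=0.0,
        )
        if self.trial_duration < last:
            raise ValueError("trial_duration precedes last event offset")


class EventReportError(ValueError):
    """Malformed event-report file."""


def _fmt(value: float) -> str:
    # locale-independent, trims trailing zeros but keeps sub-ms precision
    return f"{value:.4f}".rstrip("0").rstrip(".")


def write_event_report(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Serialize trials as the TSV event-report dialect (deterministic order)."""
    lines = ["\t".join(COLUMNS)]
    for trial in trials:
        base = [trial.participant_id, trial.group, trial.font,
                trial.text_id, trial.trial_id]
        rows: list[tuple[float, list[str]]] = []
        rows.append((-1.0, base + ["trial", "0", _fmt(trial.trial_duration),
                                   "", "", "", ""]))
        for f in trial.fixations:
            rows.append((f.onset, base + ["fixation", _fmt(f.onset), _fmt(f.offset),
                                          _fmt(f.x), _fmt(f.y), "", ""]))
        for s in trial.saccades:
            rows.append((s.onset, base + ["saccade", _fmt(s.onset), _fmt(s.offset),
                                          _fmt(s.x0), _fmt(s.y0),
                                          _fmt(s.x1), _fmt(s.y1)]))
        for b in trial.blinks:
            rows.append((b.onset, base + ["blink", _fmt(b.onset), _fmt(b.offset),
                                          "", "", "", ""]))
        rows.sort(key=lambda r: r[0])
        lines.extend("\t".join(r[1]) for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_report(
    path: str | Path,
    geometry: DisplayGeometry | None = None,
    strict: bool = False,
) -> list[TrialRecord]:
    """Parse an event report into one :class:`TrialRecord` per trial id.

    Rows are grouped by the ``trial`` column; events are sorted by onset.
    Malformed rows raise :class:`EventReportError` with their line number in
    strict mode and are skipped with a warning count otherwise (the count is
    attached to the exception message in strict mode only).
    """
    geometry = geometry or DisplayGeometry()
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise EventReportError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise EventReportError(f"{path}: missing mandatory columns {missing}")
    idx = {c: header.index(c) for c in COLUMNS}

    trials: dict[str, TrialRecord] = {}
    bad: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            key = parts[idx["trial"]]
            if key not in trials:
                trials[key] = TrialRecord(
                    participant_id=parts[idx["participant"]],
                    group=parts[idx["group"]],
                    font=parts[idx["font"]],
                    text_id=parts[idx["text"]],
                    geometry=geometry,
                )
            t = trials[key]
            etype = parts[idx["event_type"]]
            onset = float(parts[idx["onset"]])
            offset = float(parts[idx["offset"]])
            if etype == "trial":
                t.trial_duration = offset
            elif etype == "fixation":
                t.fixations.append(FixationEvent(
                    onset, offset,
                    float(parts[idx["x0"]]), float(parts[idx["y0"]])))
            elif etype == "saccade":
                t.saccades.append(SaccadeEvent(
                    onset, offset,
                    float(parts[idx["x0"]]), float(parts[idx["y0"]]),
                    float(parts[idx["x1"]]), float(parts[idx["y1"]])))
            elif etype == "blink":
                t.blinks.append(BlinkEvent(onset, offset))
            else:
                raise ValueError(f"unknown event type {etype!r}")
        except (IndexError, ValueError) as exc:
            if strict:
                raise EventReportError(f"{path}:{lineno}: {exc}") from exc
            bad.append(lineno)

    out = []
    for t in trials.values():
        t.fixations.sort(key=lambda e: e.onset)
        t.saccades.sort(key=lambda e: e.onset)
        t.blinks.sort(key=lambda e: e.onset)
        if t.trial_duration == 0.0 and (t.fixations or t.saccades or t.blinks):
            t.trial_duration = max(
                ev.offset for ev in (*t.fixations, *t.saccades, *t.blinks))
        t.validate()
        out.append(t)
    return out
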