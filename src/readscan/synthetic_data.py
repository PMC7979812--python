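"""Synthetic multi-line text layouts and two-group reading scanpath cohorts.

The generator emulates silent paragraph reading of standardized ~150-word
texts (about 84 characters per line) by two reader profiles whose parameters
are set from the reported group medians of adult readers with and without
dyslexia: median fixation duration 202 vs 224 ms, line-initial fixation
medians 216 vs 256 ms (implemented as a +14 / +32 ms inflation of the first
fixation on a new line), directional-deviation rates 0.441 vs 1.003 per
trial with downward deviations for the dyslexia profile and upward for the
control profile.

The walk advances word by word with skipping, refixations, regressions
(equal per-step hazard in both default profiles), a return-sweep at every
line break that lands mid-line with some probability ("undersweep") followed
by a leftward corrective saccade, and Poisson-count directional-deviation
excursions inserted as an excursion/return pair between two forward
fixations.  Fixation durations are lognormal around the profile median;
saccades take a fixed 25 ms; blinks are inserted into random inter-fixation
gaps.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .event_io import (BlinkEvent, DisplayGeometry, FixationEvent, TrialRecord)
from .layout import TextLayout, WordBox

SACCADE_GAP_MS = 25.0     # nominal saccade duration between fixations
READING_ONSET_MS = 420.0  # text appears / reading begins
TAIL_MS = 420.0           # reading end to space-bar press


# ---------------------------------------------------------------------------
# layout generation
# ---------------------------------------------------------------------------

def generate_layout(
    n_words: int,
    chars_per_line: float = 83.57,
    char_px: float = 10.8,
    line_spacing_px: float = 50.0,
    char_height_px: float = 20.0,
    margin_x_px: float = 30.0,
    margin_y_px: float = 40.0,
    display_width: float = 1024.0,
    display_height: float = 768.0,
    word_length_lambda: float = 4.0,
    seed: int = 0,
    text_id: str = "",
) -> TextLayout:
    """Generate a left-aligned multi-line layout with random word lengths.

    Word lengths are 1 + Poisson(``word_length_lambda``) characters,
    truncated so no word exceeds the line length.  Words are wrapped
    greedily at ``chars_per_line`` with single-character spaces.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if min(chars_per_line, char_px, line_spacing_px, char_height_px) <= 0:
        raise ValueError("geometry parameters must be positive")
    rng = np.random.default_rng(seed)
    max_len = max(2, int(chars_per_line) - 1)
    lengths = 1 + rng.poisson(word_length_lambda, size=n_words)
    lengths = np.clip(lengths, 1, max_len)

    words: list[WordBox] = []
    line, cursor = 0, 0.0  # cursor in characters
    for i, length in enumerate(lengths):
        if cursor > 0 and cursor + length > chars_per_line:
            line += 1
            cursor = 0.0
        x0 = margin_x_px + cursor * char_px
        y0 = margin_y_px + line * line_spacing_px
        words.append(WordBox(
            word_index=i, line_index=line,
            x0=x0, y0=y0,
            x1=x0 + length * char_px, y1=y0 + char_height_px,
            char_count=int(length),
        ))
        cursor += length + 1  # one-character space
    layout = TextLayout(words, display_width=display_width,
                        display_height=display_height, text_id=text_id)
    if layout.words[-1].y1 > display_height:
        raise ValueError("layout exceeds display height; reduce n_words or spacing")
    return layout


# ---------------------------------------------------------------------------
# reader profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReaderProfile:
    """Generative parameters of one reader group."""

    fixdur_median: float = 202.0        # ms, median of the lognormal
    fixdur_sigma: float = 0.32          # log-scale spread
    line_initial_inflation: float = 14.0  # ms added to line-initial fixations
    refixation_prob: float = 0.15       # per fixated word
    skip_prob: float = 0.25             # per word during forward advance
    regression_prob: float = 0.06       # per advance decision
    deviation_rate: float = 0.441       # Poisson mean per trial
    deviation_angle_mode: str = "up"    # "down" | "up"
    undersweep_prob: float = 0.10       # per line break
    blink_rate: float = 1.2             # Poisson mean per trial
    landing_noise_sd: float = 6.0       # px, horizontal landing jitter
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in ("refixation_prob", "skip_prob", "regression_prob",
                  "undersweep_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if self.fixdur_median < 50:
            raise ValueError("fixdur_median must be >= 50 ms")
        if self.deviation_rate < 0 or self.blink_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.deviation_angle_mode not in ("down", "up"):
            raise ValueError("deviation_angle_mode must be 'down' or 'up'")


def control_profile(**overrides) -> ReaderProfile:
    """Default profile of the group without dyslexia."""
    return replace(ReaderProfile(), **overrides)


def dyslexia_profile(**overrides) -> ReaderProfile:
    """Default profile of the dyslexia group (longer fixations, fewer skips,
    more refixations, more frequent — and downward — directional deviations)."""
    base = ReaderProfile(
        fixdur_median=224.0,
        line_initial_inflation=32.0,
        refixation_prob=0.35,
        skip_prob=0.10,
        regression_prob=0.06,
        deviation_rate=1.003,
        deviation_angle_mode="down",
        undersweep_prob=0.20,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Generator-side ground truth for one simulated trial."""

    target_words: list[int] = field(default_factory=list)  # per planned fixation
    n_return_sweeps: int = 0
    n_undersweeps: int = 0
    n_deviations: int = 0
    n_regressions: int = 0
    n_blinks: int = 0
    n_refixations: int = 0


@dataclass
class _Fix:
    word: int          # targeted word index (the word aimed at, pre-noise)
    x: float
    y: float
    dur: float
    line_initial: bool = False


def _plan_walk(layout: TextLayout, profile: ReaderProfile,
               rng: np.random.Generator, truth: SimTruth) -> list[_Fix]:
    noise = profile.landing_noise_sd

    def duration(inflate: bool = False) -> float:
        d = rng.lognormal(math.log(profile.fixdur_median), profile.fixdur_sigma)
        if inflate:
            d += profile.line_initial_inflation
        return d

    def land(word: int, dx: float = 0.0) -> tuple[float, float]:
        cx, cy = layout.words[word].center
        return (cx + dx + rng.normal(0.0, noise),
                cy + rng.normal(0.0, 0.6 * noise))

    plan: list[_Fix] = []

    def fixate(word: int, line_initial: bool = False, dx: float = 0.0) -> _Fix:
        x, y = land(word, dx)
        f = _Fix(word, x, y, duration(line_initial), line_initial)
        plan.append(f)
        return f

    def maybe_refixate(word: int) -> None:
        # within-word jump to the other side of the word: nearly horizontal
        # (no vertical-deviation look-alikes), always above the minimum
        # saccade amplitude, and confined to the word box.  Words too short
        # to host such a jump are not refixated, as in real reading.
        w = layout.words[word]
        while rng.random() < profile.refixation_prob:
            prev = plan[-1]
            room_left = prev.x - (w.x0 + 2.0)
            room_right = (w.x1 - 2.0) - prev.x
            room = max(room_left, room_right)
            if room < 18.0:
                return
            sign = 1.0 if room_right >= room_left else -1.0
            d = float(rng.uniform(18.0, room))
            f = _Fix(word, prev.x + sign * d,
                     prev.y + rng.normal(0.0, 1.2), duration())
            plan.append(f)
            truth.n_refixations += 1

    for line in range(layout.line_count):
        first, last = layout.line_word_span(line)
        if line == 0:
            fixate(first, line_initial=True)
        else:
            # return-sweep from the previous line's final fixation
            n_line = last - first + 1
            undersweep = (rng.random() < profile.undersweep_prob and n_line >= 8)
            if undersweep:
                landing = first + 4 + int(rng.integers(0, 3))
                fixate(landing)                        # short-of-target landing
                fixate(first, line_initial=True)       # leftward corrective
                truth.n_undersweeps += 1
            else:
                fixate(first, line_initial=True)
                truth.n_return_sweeps += 1
        maybe_refixate(plan[-1].word)

        current = first
        while current < last:
            nxt = current + 1
            while nxt < last and rng.random() < profile.skip_prob:
                nxt += 1
            fixate(nxt)
            maybe_refixate(nxt)
            current = nxt
    return plan


def _insert_regressions(plan: list[_Fix], layout: TextLayout,
                        profile: ReaderProfile, rng: np.random.Generator,
                        truth: SimTruth) -> list[_Fix]:
    """Insert regressive revisits with an equal hazard per transition.

    ``regression_prob`` is the intended per-saccade regression probability.
    Insertions interrupt same-line, non-backward transitions of the planned
    walk (line sweeps and their correctives are left intact) with a
    one-fixation leftward revisit of a previously read or skipped word on
    the same line, up to 8 words back; the eyes then jump onward to the
    already-planned next fixation.
    The per-slot insertion rate is rescaled by the trial's share of eligible
    transitions so that E[regressions / saccades] equals ``regression_prob``
    regardless of the walk's composition — profiles generating more saccades
    therefore accumulate proportionally more regressions while the
    regression *probability* stays matched across profiles.
    """
    if profile.regression_prob <= 0 or len(plan) < 2:
        return plan

    def slot_candidates(i: int) -> list[int]:
        f, nxt = plan[i], plan[i + 1]
        line = layout.words[f.word].line_index
        if layout.words[nxt.word].line_index != line or nxt.word < f.word:
            return []
        return [w for w in range(max(0, f.word - 8), f.word)
                if layout.words[w].line_index == line
                and f.x - layout.words[w].center[0] >= 40.0]

    n_transitions = len(plan) - 1
    candidates = [slot_candidates(i) for i in range(n_transitions)]
    n_eligible = sum(bool(c) for c in candidates)
    if n_eligible == 0:
        return plan
    p = profile.regression_prob
    q = min(1.0, p * n_transitions / ((1.0 - p) * n_eligible))

    out: list[_Fix] = []
    for i, f in enumerate(plan):
        out.append(f)
        if i + 1 >= len(plan) or not candidates[i]:
            continue
        if rng.random() >= q:
            continue
        target = int(rng.choice(candidates[i]))
        cx, cy = layout.words[target].center
        dur = rng.lognormal(math.log(profile.fixdur_median),
                            profile.fixdur_sigma)
        out.append(_Fix(target,
                        cx + rng.normal(0.0, profile.landing_noise_sd),
                        cy + rng.normal(0.0, 0.6 * profile.landing_noise_sd),
                        dur))
        truth.n_regressions += 1
    return out


def _insert_deviations(plan: list[_Fix], layout: TextLayout,
                       profile: ReaderProfile, rng: np.random.Generator,
                       truth: SimTruth) -> list[_Fix]:
    """Insert Poisson-count excursion/return pairs between forward fixations.

    The excursion jumps down-left (or up-left) by ~35-50 px so its saccade
    angle falls well inside the 35-145 deg deviation band, lands between text
    lines, and the return to the already-planned next fixation stays shallow
    (< 35 deg) so exactly one atypical saccade is produced per insertion.
    """
    k = rng.poisson(profile.deviation_rate)
    if k == 0:
        return plan
    eligible = [
        i for i in range(len(plan) - 1)
        if layout.words[plan[i].word].line_index
        == layout.words[plan[i + 1].word].line_index
        and plan[i + 1].word > plan[i].word
        and (plan[i + 1].x - plan[i].x) >= 60.0
    ]
    if not eligible:
        return plan
    k = min(k, len(eligible))
    chosen = sorted(rng.choice(len(eligible), size=k, replace=False),
                    reverse=True)
    sign = 1.0 if profile.deviation_angle_mode == "down" else -1.0
    for j in chosen:
        i = eligible[j]
        launch = plan[i]
        dx = -float(np.clip(22.0 + rng.normal(0.0, 3.0), 22.0, 30.0))
        dy = sign * float(np.clip(29.0 + rng.normal(0.0, 2.0), 26.0, 32.0))
        dur = rng.lognormal(math.log(140.0), 0.25)
        exc = _Fix(launch.word, launch.x + dx, launch.y + dy, dur)
        plan.insert(i + 1, exc)
        truth.n_deviations += 1
    return plan


def simulate_trial(
    layout: TextLayout,
    profile: ReaderProfile,
    seed: int | None = None,
    geometry: DisplayGeometry | None = None,
    participant_id: str = "sim",
    group: str = "control",
    font: str = "TNR",
    return_truth: bool = False,
):
    """Simulate one reading trial over ``layout`` for one reader profile.

    Returns a :class:`TrialRecord` with fixations and blinks (saccades are
    re-derived downstream from the cleaned fixation sequence).  With
    ``return_truth=True`` also returns the generator-side event bookkeeping
    used as ground truth in tests.
    """
    if seed is None:
        seed = profile.seed if profile.seed is not None else 0
    geometry = geometry or DisplayGeometry()
    rng = np.random.default_rng(seed)
    truth = SimTruth()

    plan = _plan_walk(layout, profile, rng, truth)
    plan = _insert_regressions(plan, layout, profile, rng, truth)
    plan = _insert_deviations(plan, layout, profile, rng, truth)
    truth.target_words = [f.word for f in plan]

    # blinks into random inter-fixation gaps
    n_gaps = len(plan) - 1
    n_blinks = min(rng.poisson(profile.blink_rate), max(n_gaps, 0))
    blink_gaps = set(rng.choice(n_gaps, size=n_blinks, replace=False)) \
        if n_blinks > 0 else set()
    truth.n_blinks = len(blink_gaps)

    fixations: list[FixationEvent] = []
    blinks: list[BlinkEvent] = []
    t = READING_ONSET_MS
    for i, f in enumerate(plan):
        fixations.append(FixationEvent(t, t + f.dur, f.x, f.y))
        t += f.dur
        if i in blink_gaps:
            bdur = float(rng.uniform(80.0, 250.0))
            blinks.append(BlinkEvent(t + 10.0, t + 10.0 + bdur))
            t += 20.0 + bdur
        t += SACCADE_GAP_MS

    trial = TrialRecord(
        participant_id=participant_id, group=group, font=font,
        text_id=layout.text_id or "text", fixations=fixations,
        blinks=blinks, geometry=geometry,
        trial_duration=(fixations[-1].offset if fixations else 0.0) + TAIL_MS,
    )
    trial.validate()
    return (trial, truth) if return_truth else trial


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort layout: participants x texts x fonts."""

    n_control: int = 10
    n_dyslexia: int = 10
    n_texts: int = 9
    fonts: tuple[str, ...] = ("TNR", "OpenDyslexic")
    profiles: dict[str, ReaderProfile] = field(default_factory=lambda: {
        "control": control_profile(),
        "dyslexia": dyslexia_profile(),
    })
    master_seed: int = 0
    n_words_range: tuple[int, int] = (140, 160)

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_dyslexia < 0:
            raise ValueError("group sizes must be non-negative")


# wider glyphs for the dyslexia-friendly font
_FONT_CHAR_PX = {"TNR": 10.8, "OpenDyslexic": 11.6}


def _derived_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def cohort_layouts(spec: CohortSpec) -> dict[tuple[str, str], TextLayout]:
    """One layout per (text, font) pair, deterministic in the master seed."""
    layouts: dict[tuple[str, str], TextLayout] = {}
    for ti in range(spec.n_texts):
        text_id = f"T{ti + 1:02d}"
        for fi, font in enumerate(spec.fonts):
            seed = _derived_seed(spec.master_seed, 7001, ti, fi)
            rng = np.random.default_rng(seed)
            n_words = int(rng.integers(*spec.n_words_range, endpoint=True))
            layouts[(text_id, font)] = generate_layout(
                n_words,
                char_px=_FONT_CHAR_PX.get(font, 11.0),
                seed=seed + 1,
                text_id=text_id,
            )
    return layouts


def simulate_cohort(
    spec: CohortSpec,
    geometry: DisplayGeometry | None = None,
) -> tuple[list[TrialRecord], dict[tuple[str, str], TextLayout]]:
    """Simulate every participant reading every text in every font.

    Per-trial seeds are derived deterministically from the master seed and
    the (group, participant, text, font) coordinates, so any subset of the
    cohort can be re-simulated identically.
    """
    geometry = geometry or DisplayGeometry()
    layouts = cohort_layouts(spec)
    trials: list[TrialRecord] = []
    groups = [("control", spec.n_control, "C"), ("dyslexia", spec.n_dyslexia, "D")]
    for gi, (group, n, prefix) in enumerate(groups):
        profile = spec.profiles[group]
        for pi in range(n):
            pid = f"{prefix}{pi + 1:02d}"
            for ti in range(spec.n_texts):
                text_id = f"T{ti + 1:02d}"
                for fi, font in enumerate(spec.fonts):
                    seed = _derived_seed(spec.master_seed, gi, pi, ti, fi)
                    trials.append(simulate_trial(
                        layouts[(text_id, font)], profile, seed=seed,
                        geometry=geometry, participant_id=pid,
                        group=group, font=font,
                    ))
    return trials, layouts
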