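from __future__ import annotations

import numpy as np
import pytest

from readscan.event_io import (BlinkEvent, DisplayGeometry, FixationEvent,
                               TrialRecord)
from readscan.interest_mapping import build_interest_areas
from readscan.synthetic_data import generate_layout


@pytest.fixture(scope="session")
def geometry() -> DisplayGeometry:
    return DisplayGeometry()


@pytest.fixture(scope="session")
def layout150():
    return generate_layout(150, seed=1, text_id="T1")


@pytest.fixture(scope="session")
def areas150(layout150):
    return build_interest_areas(layout150)


def make_trial(fixes, blinks=(), duration=None,
               geometry=DisplayGeometry(), **labels) -> TrialRecord:
    """Build a trial from (onset, offset, x, y) fixation tuples."""
    fixations = [FixationEvent(*f) for f in fixes]
    blink_events = [BlinkEvent(*b) for b in blinks]
    if duration is None:
        last = max((e.offset for e in (*fixations, *blink_events)),
                   default=0.0)
        duration = last + 500.0
    defaults = dict(participant_id="p1", group="control", font="TNR",
                    text_id="T1")
    defaults.update(labels)
    return TrialRecord(fixations=fixations, blinks=blink_events,
                       geometry=geometry, trial_duration=duration,
                       **defaults)


@pytest.fixture
def trial_factory():
    return make_trial


def seeds_for(n: int, label: int) -> list[int]:
    """Independent per-replicate seeds derived through a SeedSequence."""
    return [int(s) for s in
            np.random.SeedSequence(label).generate_state(n) % (2 ** 31)]
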