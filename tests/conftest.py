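from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from abpauto.io_formats import ABPTrace, BPReading, JournalEvent

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

T0 = datetime(2016, 3, 1, 7, 0)


def make_trace(rows, subject_id="S1", start=T0, step_min=15):
    """Build a trace from (sbp, dbp, hr) rows at a fixed cadence, or from
    (minute_offset, sbp, dbp, hr) rows at explicit offsets."""
    readings = []
    for i, row in enumerate(rows):
        if len(row) == 4:
            off, s, d, h = row
        else:
            off = i * step_min
            s, d, h = row
        readings.append(
            BPReading(start + timedelta(minutes=off), float(s), float(d), float(h))
        )
    return ABPTrace(subject_id, tuple(readings))


def event(kind, hh, mm=0, day=1, subject_id="S1"):
    return JournalEvent(subject_id, kind, datetime(2016, 3, day, hh, mm))


@pytest.fixture
def flat_trace():
    """26 h-cadence readings at 130/80, HR 70 — featureless."""
    return make_trace([(130, 80, 70)] * 26, step_min=60)
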