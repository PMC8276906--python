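"""Shared fixtures: schedules, profiles, and windowed synthetic sessions."""

import numpy as np
import pytest
from hypothesis import settings

import stressbci as sb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from stressbci.session import ConditionSegment, SessionSchedule


@pytest.fixture(scope="session")
def default_profile():
    return sb.session.sample_profile("L1", "ASD", seed=42)


@pytest.fixture(scope="session")
def full_recording(default_profile):
    """One full default session (120 s baseline + 4 blocks, 30 s rests)."""
    return sb.generate_recording(default_profile, sb.make_schedule(30.0))


@pytest.fixture(scope="session")
def full_windows(full_recording):
    """Filtered 1 s windows of the full session: 120/360/400/400 per class."""
    return sb.extract_windows(sb.bandpass(full_recording), 1.0)


def short_schedule(baseline=60.0, stressor=45.0, breathing=100.0, rest=5.0):
    """A reduced-duration schedule with the same block structure."""
    segs = []
    t = 0.0

    def push(label, dur):
        nonlocal t
        if dur > 0:
            segs.append(ConditionSegment(label, t, dur))
            t += dur

    push("baseline", baseline)
    for block in range(4):
        push("stressor", stressor)
        push("rest", rest)
        push("unguided" if block % 2 == 0 else "guided", breathing)
        push("rest", rest)
    return SessionSchedule(tuple(segs))


@pytest.fixture(scope="session")
def short_windows(default_profile):
    """Windows from a reduced-duration session, for fast training tests."""
    rec = sb.generate_recording(default_profile, short_schedule())
    return sb.extract_windows(sb.bandpass(rec), 1.0)
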