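import numpy as np
import pytest

from sleepswitch.behavior import compute_speed
from sleepswitch.traces import ActivityTrace, StimulusEvent, StimulusSchedule


def make_trace(x, fly_id="f0", dt=1.0):
    x = np.asarray(x, dtype=float)
    return compute_speed(ActivityTrace(fly_id=fly_id, t=np.arange(len(x)) * dt, x=x))


def trace_from_speed(speeds, fly_id="f0", dt=1.0):
    """Build a trace whose |dx|/dt equals the requested speed series
    (speeds[0] is ignored; the first frame's speed is defined as 0)."""
    speeds = np.asarray(speeds, dtype=float)
    x = np.concatenate([[0.0], np.cumsum(speeds[1:] * dt)])
    tr = make_trace(x, fly_id=fly_id, dt=dt)
    assert np.allclose(tr.speed[1:], speeds[1:])
    return tr


def schedule(onsets, light=None):
    light = light or [False] * len(onsets)
    return StimulusSchedule(events=[
        StimulusEvent(stim_id=i, onset_s=float(o), light_on=bool(l))
        for i, (o, l) in enumerate(zip(onsets, light))
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across tests (1 day, 12 flies)."""
    from sleepswitch.synth import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_flies=12, days=1, seed=42)
    return simulate_cohort(cfg)
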