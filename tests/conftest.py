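import numpy as np
import pandas as pd
import pytest

from somnoscore.epoch_data import (ActivityEpochSeries, HypnogramSeries,
                                   SleepWakeSeries)

T0 = pd.Timestamp("2020-01-01 22:00:00")


@pytest.fixture
def t0():
    return T0


def make_activity(counts, missing=None, start=T0, pid="P000"):
    return ActivityEpochSeries(pid, start, np.asarray(counts, dtype=float), missing)


def make_sleepwake(states, missing=None, hybrid=None, start=T0, pid="P000"):
    """states given as a string like 'SSWS' or a sequence of 0/1."""
    if isinstance(states, str):
        states = [1 if c == "S" else 0 for c in states]
    return SleepWakeSeries(pid, start, np.asarray(states, dtype=np.int8),
                           missing_mask=missing, hybrid_mask=hybrid)


def make_hypnogram(stages, start=T0, pid="P000"):
    return HypnogramSeries(pid, start, np.asarray(stages, dtype="U3"))


@pytest.fixture
def activity_factory():
    return make_activity


@pytest.fixture
def sleepwake_factory():
    return make_sleepwake


@pytest.fixture
def hypnogram_factory():
    return make_hypnogram
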