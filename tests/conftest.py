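import warnings

import numpy as np
import pytest

import myoslice as ms
from myoslice.transduce import trace_to_force


@pytest.fixture
def tissue():
    return ms.TissueParams()


@pytest.fixture
def transducer():
    return ms.SpringTransducer()


@pytest.fixture
def paced_trace(tissue):
    """12-beat paced recording at 0.2 Hz with calibrated noise, seed 1."""
    schedule = ms.pacing_schedule(0.2, 60.0)
    config = ms.SimulationConfig(duration=64.0, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ms.SaturationWarning)
        trace = ms.simulate_run(tissue, schedule, config)
    return trace, schedule


@pytest.fixture
def noise_free_trace(tissue):
    schedule = ms.pacing_schedule(0.2, 60.0)
    config = ms.SimulationConfig(duration=64.0, seed=1, noise=False)
    trace = ms.simulate_run(tissue, schedule, config)
    return trace, schedule


def force_series(trace):
    return trace_to_force(trace), trace.time
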