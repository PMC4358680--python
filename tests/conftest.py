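import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cortisim import ModelParameters, Trace

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basal() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def trace_factory():
    """Build a Trace from raw voltage samples (mV) at a given dt (ms)."""

    def make(v, dt: float = 0.1) -> Trace:
        return Trace(voltages=np.asarray(v, dtype=float), dt=dt)

    return make


def naive_event_scan(v, base, threshold, rearm):
    """Independent sample-by-sample reference detector used as an oracle.

    Deliberately re-implements the threshold/re-arm semantics with plain
    Python control flow, independent of the package's kernel.
    """
    events = []
    in_event = False
    start = 0
    peak = None
    for i in range(len(v)):
        if not in_event:
            if v[i] >= base[i] + threshold:
                in_event = True
                start = i
                peak = v[i]
        else:
            if v[i] < base[i] + rearm:
                events.append((start, i, peak, False))
                in_event = False
            else:
                peak = max(peak, v[i])
    if in_event:
        events.append((start, len(v), peak, True))
    return events
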