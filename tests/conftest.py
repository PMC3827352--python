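import numpy as np
import pytest

from tastecalc.trace import StimulusEpoch, Trace


@pytest.fixture
def epoch():
    return StimulusEpoch("SAC", 2.0, 30.0, 60.0)


def make_trace(values, cell_id="cell0", epochs=(), dt=1.0):
    values = np.asarray(values, dtype=float)
    return Trace(
        cell_id=cell_id,
        time=np.arange(values.size, dtype=float) * dt,
        ratio=values,
        epochs=list(epochs),
    )


@pytest.fixture
def square_pulse_trace(epoch):
    """Baseline 1.0 with a clean +0.5 square pulse on samples 62..71 (10 s)."""
    vals = np.ones(150)
    vals[62:72] = 1.5
    return make_trace(vals, epochs=[epoch])
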