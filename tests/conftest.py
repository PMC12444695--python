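import numpy as np
import pytest

from bedmotion.sensor_io import SensorRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_recording(t, angle, pitch, ax=None, ay=None, az=None, patient_id="p1"):
    t = np.asarray(t, dtype=float)
    n = t.size
    zeros = np.zeros(n)
    return SensorRecording(
        patient_id,
        t,
        np.asarray(angle, dtype=float),
        np.asarray(pitch, dtype=float),
        zeros if ax is None else np.asarray(ax, dtype=float),
        zeros if ay is None else np.asarray(ay, dtype=float),
        (zeros + 1.0) if az is None else np.asarray(az, dtype=float),
    )


@pytest.fixture
def recording_factory():
    return make_recording
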