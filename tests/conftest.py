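import numpy as np
import pytest

from panometry import load_table2_counts
from panometry.topo import FILL_STEPS_ML, N_CHANNELS, FlipStudy


@pytest.fixture(scope="session")
def table2():
    return load_table2_counts()


def make_constant_study(
    egj_diameter: float = 16.0,
    pressure: float = 50.0,
    body_diameter: float = 20.0,
    steps=FILL_STEPS_ML,
    sample_hz: float = 10.0,
    dwell_s: float = 40.0,
) -> FlipStudy:
    """A flat study: constant diameters and pressure within each fill step."""
    n_per = int(round(dwell_s * sample_hz))
    n = n_per * len(steps)
    diameters = np.full((n, N_CHANNELS), body_diameter, dtype=float)
    diameters[:, 12:15] = egj_diameter + 2.0
    diameters[:, 13] = egj_diameter
    diameters[:, 15] = 25.0
    return FlipStudy(
        time=np.arange(n) / sample_hz,
        fill_volume=np.repeat(np.asarray(steps, dtype=float), n_per),
        bag_pressure=np.full(n, pressure, dtype=float),
        diameters=diameters,
        egj_channel_range=(12, 14),
    )


@pytest.fixture
def constant_study():
    return make_constant_study()
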