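import numpy as np
import pandas as pd
import pytest

from rtfit import TimeCourseDataset


@pytest.fixture(scope="session")
def constant_dataset():
    """48 points of pure noise around a constant level: the RTF with both
    amplitudes fixed to zero reduces to a Gaussian location model here."""
    rng = np.random.default_rng(7)
    times = np.tile(np.arange(8.0), 6)
    return TimeCourseDataset(pd.DataFrame({
        "time": times,
        "dose": 1.0,
        "condition": "toy",
        "replicate": np.repeat(np.arange(6), 8),
        "value": rng.normal(2.0, 0.5, times.size),
    }))


@pytest.fixture(scope="session")
def unit_toy_dataset():
    """Deterministic table with y in [0, 1], times 0..10, doses 1..7 —
    matches the worked bound examples for the default parameter space."""
    times = np.arange(11.0)
    doses = np.arange(1.0, 8.0)
    rows = []
    for d in doses:
        rows.append(pd.DataFrame({
            "time": times, "dose": d, "condition": "c", "replicate": 1,
            "value": np.linspace(0.0, 1.0, times.size),
        }))
    return TimeCourseDataset(pd.concat(rows, ignore_index=True))
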