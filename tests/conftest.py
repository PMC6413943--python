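from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sharktrace.synthetic import SimulationConfig, simulate

EPOCH = pd.Timestamp("2012-01-01")


def det_frame(rows):
    """Build a canonical-ish detection frame from (tag, station, seconds) tuples."""
    return pd.DataFrame(
        {
            "tag_id": [r[0] for r in rows],
            "station_id": [r[1] for r in rows],
            "timestamp": [EPOCH + pd.Timedelta(seconds=float(r[2])) for r in rows],
        }
    )


def random_stream(rng, n=40, n_stations=3, mean_gap_s=420.0):
    """One tag's random detection stream: exponential gaps, random stations."""
    gaps = np.maximum(1, np.round(rng.exponential(mean_gap_s, size=n)))
    times = np.cumsum(gaps)
    stations = rng.integers(0, n_stations, size=n)
    return times, np.array([chr(ord("A") + s) for s in stations])


@pytest.fixture(scope="session")
def small_sim():
    """Small full-structure synthetic dataset shared across tests."""
    return simulate(SimulationConfig(n_sharks=6, study_days=30, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
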