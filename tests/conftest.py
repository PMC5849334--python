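import numpy as np
import pandas as pd
import pytest

from nmrpeaks import SimConfig, detect_peaks, group_peaks, simulate_spectra
from nmrpeaks.cwt_peaks import PEAK_COLUMNS
from nmrpeaks.grouping import FeatureGroup


@pytest.fixture(scope="session")
def sim_data():
    """Default simulated dataset (20 spectra, planted truth), seed 1."""
    return simulate_spectra(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_peaks(sim_data):
    spectra, _ = sim_data
    return detect_peaks(spectra)


@pytest.fixture(scope="session")
def sim_groups(sim_peaks):
    return group_peaks(sim_peaks).groups


def make_peaks(rows) -> pd.DataFrame:
    """Build a peak table from (sample_id, peak_index[, peak_value]) tuples."""
    recs = []
    for r in rows:
        sid, idx = r[0], r[1]
        val = r[2] if len(r) > 2 else 1.0
        recs.append(
            {
                "sample_id": sid,
                "peak_index": int(idx),
                "ppm": 10.0 - idx * 0.001,
                "peak_value": float(val),
                "peak_height": float(val),
                "snr": 10.0,
                "scale": 4,
                "filled": False,
            }
        )
    return pd.DataFrame(recs)[PEAK_COLUMNS]


def make_group(fid, rows) -> FeatureGroup:
    peaks = make_peaks(rows)
    return FeatureGroup(fid, peaks, peaks.iloc[0:0].copy())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
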