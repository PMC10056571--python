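import numpy as np
import pandas as pd
import pytest

from rprime.io import Calibration
from rprime.synth import WaveformParams, gen_waveform


@pytest.fixture
def calibration() -> Calibration:
    return Calibration()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def clean_strip():
    """Noiseless default rSr' strip (theta_up=16, alpha=24, h=3 mm) + truth."""
    return gen_waveform(WaveformParams(n_beats=5))


@pytest.fixture
def feature_frame() -> pd.DataFrame:
    """Small hand-built feature table with one unmeasurable patient."""
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "beta_deg": [53.1, 30.0, np.nan],
            "alpha_deg": [41.4, 20.0, np.nan],
            "dbt5_ms": [247.5, 100.0, np.nan],
            "dbtiso_ms": [107.9, 60.0, np.nan],
            "ratio": [1.4, 0.9, np.nan],
            "measurable_ii": [True, True, False],
            "measurable_iii": [True, False, False],
            "measurable_iv": [False, False, False],
            "scbpt_label": [1, 0, 0],
        }
    )
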