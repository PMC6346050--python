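import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from striatune import synth

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from striatune.tuning import TuningCurve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def freq_grid():
    """Quarter-octave recording grid, 2 to ~45 kHz."""
    return np.asarray(synth.DEFAULT_FREQ_GRID_KHZ)


@pytest.fixture
def gaussian_curve(freq_grid):
    """Factory for noiseless Gaussian tuning curves on the recording grid."""

    def make(A=10.0, f0_khz=16.0, sigma=0.5, B=0.0):
        x = np.log2(freq_grid)
        rates = A * np.exp(-0.5 * (x - np.log2(f0_khz)) ** 2 / sigma**2) + B
        return TuningCurve(freq_grid, rates)

    return make


@pytest.fixture
def onset_unit_trials():
    """Small control-only trial table plus a matching onset-response unit."""
    spec = synth.UnitSpec(
        unit_id=0,
        baseline_rate_hz=5.0,
        tuning_A_hz=30.0,
        tuning_sigma_oct=0.6,
        kernel=synth.ResponseKernel("onset", latency_s=0.015, duration_s=0.025),
    )
    n = 60
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "onset_s": 1.0 + 2.0 * np.arange(n),
            "freq_khz": 2.0 ** spec.tuning_f0_log2khz,
            "intensity_db": 60.0,
            "duration_s": 0.1,
            "light_on": False,
        }
    )
    return spec, trials
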