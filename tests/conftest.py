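import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from aadkit.pipeline import ExperimentConfig, run_pipeline  # noqa: E402


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_config():
    """A short Case-1 decoding trial configuration for fast end-to-end runs."""
    return ExperimentConfig(duration_s=20.0, tuning_duration_s=10.0,
                            switch_times_s=(10.0,), smoother_window_s=5.0,
                            forward_lag_s=0.5, seed=11)


@pytest.fixture(scope="session")
def small_pipeline_result(small_config):
    return run_pipeline(small_config)
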