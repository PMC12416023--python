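import numpy as np
import pytest

from armkin.limb_model import default_model
from armkin.pipeline import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def model():
    return default_model(1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition experiment, shared across tests."""
    return run_experiment(ExperimentConfig(master_seed=11))


@pytest.fixture(scope="session")
def zero_noise_run():
    """End-to-end run with all stochastic noise off (latency and device frame
    offsets kept); orientation smoothing disabled because there is nothing to
    smooth."""
    cfg = ExperimentConfig(
        n_participants=2, noise_scale=0.0, cf_smoothing_alpha=1.0, master_seed=5
    )
    return run_experiment(cfg)
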