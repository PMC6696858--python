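import numpy as np
import pytest

from paee.simulate import SimConfig, simulate_cohort, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort():
    """Default 19-participant cohort, fixed seed."""
    return simulate_cohort(SimConfig(seed=101))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A small noiseless study bundle on disk, shared across tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = SimConfig(seed=42, n_participants=6, enrichment_noise_sd=0.0)
    truth = simulate_study(cfg, out)
    return out, cfg, truth
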