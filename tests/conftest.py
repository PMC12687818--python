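import numpy as np
import pytest

from hybridsurv import RunConfig, run_pipeline
from hybridsurv import simulate


@pytest.fixture(scope="session")
def demo():
    """One full pipeline run on the default 600-bird cohort, shared across
    tests (randomized search kept small; it does not change any contract
    under test)."""
    cfg = RunConfig(seed=42, n_birds=600, n_candidates=4, n_boot=400)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simulate.SimConfig(n_birds=300, seed=5)
    birds, traits, detections = simulate.generate_cohort(cfg)
    return cfg, birds, traits, detections


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
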