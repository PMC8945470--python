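import numpy as np
import pytest

from plantarsites import fixture_suite, run_pipeline
from plantarsites.config import PipelineConfig


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def benign_small():
    """Three benign fixtures shared across unit tests."""
    return fixture_suite("benign", 3, seed=7)


@pytest.fixture(scope="session")
def benign_results(benign_small):
    """Pipeline results paired with their fixtures."""
    return [(f, run_pipeline(f.scene)) for f in benign_small]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
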