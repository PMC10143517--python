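import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from leafspec import pipeline
from leafspec.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_study():
    """The frozen default synthetic study (150 leaves, 301 bands)."""
    return generate_dataset()


@pytest.fixture(scope="session")
def noiseless_study():
    """A small noise-free population for exact round-trip checks."""
    cfg = GeneratorConfig(n_samples=12, sensor_noise_sd=0.0,
                          assay_noise_sd=0.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_report(default_study):
    """The full two-sensor comparison on the frozen default study."""
    cfg = pipeline.ExperimentConfig()
    return pipeline.run_comparison(cfg, default_study.dataset,
                                   default_study.pigments)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
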