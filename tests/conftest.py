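import numpy as np
import pytest

from phenoflux.io import load_table3
from phenoflux.synthetic import GeneratorConfig, GenotypeProfile, default_profiles


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def aligned_profile():
    """Profile with breakpoints on the 10-s reading grid (exact round-trips)."""
    return GenotypeProfile(
        name="ALIGNED", b1=2.0, b2=8.5, s1=0.03, s2=0.05, s3=0.0275,
        night_rate=0.009, control_growth=30.0, inhibition=0.4,
        shoot_proportion=0.6, root_investment=False,
        performance_tier=3, transp_group="A",
    )


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(balance_noise_sd=0.0, morphology_cv=0.0,
                           batch_range=(1.0, 1.0))


@pytest.fixture(scope="session")
def noisy_config():
    return GeneratorConfig()
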