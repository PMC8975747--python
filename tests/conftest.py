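import numpy as np
import pytest

from cyanotransect import regimes
from cyanotransect.synthetic import TransectScenario, generate_transect


@pytest.fixture(scope="session")
def default_survey():
    """One default-scenario survey with its ground truth (seed fixed)."""
    return generate_transect(TransectScenario(seed=1))


@pytest.fixture(scope="session")
def annotated_transect(default_survey):
    df, _ = default_survey
    return regimes.annotate_regimes(df)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Noise-free, bump-free scenario: abundances sit exactly on the surface."""
    return TransectScenario(
        seed=3,
        noise_sd=0.0,
        chl_noise_sd=0.0,
        host_noise_sd=0.0,
        infection_noise_sd=0.0,
        hotspot_amplitude=0.0,
        cruise_scale={},
        cruise_pro_suppression={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
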