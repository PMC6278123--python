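import numpy as np
import pytest

from cohortval import SimConfig, generate


ZERO_DISCORDANCE = dict(
    missing_prob_cohort=0.0,
    missing_prob_surveillance=0.0,
    typo_rate=0.0,
    date_jitter_days=0,
    value_noise_sd={"CD4": 0.0, "VL": 0.0},
)


@pytest.fixture(scope="session")
def small_registries():
    """A small realistic run with all discordance channels active."""
    return generate(SimConfig(n_patients=150, seed=20260928))


@pytest.fixture(scope="session")
def clean_registries():
    """Zero-discordance limit: both sources observe identical tests."""
    return generate(SimConfig(n_patients=120, seed=7, **ZERO_DISCORDANCE))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
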