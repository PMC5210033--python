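import pytest
from hypothesis import HealthCheck, settings

import adrenadc as ad

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom without noise, shared across tests."""
    spec = ad.PhantomSpec(rician_sigma=0.0, rng_seed=7)
    series, truth = ad.generate_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noiseless_adc_map(noiseless_phantom):
    _, series, _ = noiseless_phantom
    return ad.compute_adc_map(series)
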