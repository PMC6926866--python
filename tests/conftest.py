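import pytest
from hypothesis import HealthCheck, settings

from endotwa import censor_at_lod, default_campaign_spec, generate_campaign

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def campaign():
    """A censored synthetic campaign at the default study design."""
    spec = default_campaign_spec(seed=7)
    return censor_at_lod(generate_campaign(spec), spec)
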