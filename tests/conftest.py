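import pytest
from hypothesis import HealthCheck, settings

from meatmarkers import ProteomeSpec, make_toy_proteomes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_proteomes():
    """A reproducible 5-species fixture with planted marker ground truth."""
    return make_toy_proteomes(ProteomeSpec(seed=7))
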