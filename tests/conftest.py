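import pytest
from hypothesis import HealthCheck, settings

from transplantx.syndata import generate_design

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design14():
    """The standard emulated layout: 7 treatments x 2 replicate pools."""
    return generate_design(replicates_per_treatment=2, pool_size_range=(28, 76), seed=1)
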