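import pytest
from hypothesis import HealthCheck, settings

from oncopipe.synthetic import simulate_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """Small three-chromosome reference with the default gene layout."""
    return simulate_reference(n_chromosomes=3, chrom_length=300_000, seed=11)
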