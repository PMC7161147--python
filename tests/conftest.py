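import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One default synthetic dataset: regions, linkage, SNCs, manifest."""
    from paleoreg.simulate import simulate_regions, simulate_sncs

    regions, linkage = simulate_regions(rng_seed=11)
    sncs, manifest = simulate_sncs(regions, rng_seed=12)
    return regions, linkage, sncs, manifest


@pytest.fixture(scope="session")
def counts_dataset():
    """One default synthetic count matrix with module/cluster truth."""
    from paleoreg.simulate import simulate_counts

    return simulate_counts(rng_seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
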