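import numpy as np
import pytest

from ecotransect.synthetic import TransectScenario, generate_dataset


@pytest.fixture(scope="session")
def small_scenario() -> TransectScenario:
    """Reduced-size scenario for fast end-to-end tests."""
    return TransectScenario(
        months=("Jan", "Jul"),
        total_otus=200,
        specialist_counts=(15, 15, 6, 15),
        ubiquitous_otus=30,
        library_size_range=(12_000, 15_000),
        n_rarefactions=3,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset at the reference study conditions."""
    return generate_dataset(TransectScenario(), seed=12345)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
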