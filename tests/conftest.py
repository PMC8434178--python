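import numpy as np
import pytest

from cgbvs import (
    FeatureStore,
    FixtureSpec,
    generate_cpi_dataset,
    msa_features,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A small family-sharing benchmark used across model/evaluation tests."""
    spec = FixtureSpec(
        n_targets=4,
        n_compounds=600,
        family_sizes=(2, 2),
        actives_per_target=50,
        inactives_per_target=50,
        sharing_rate=0.8,
        seed=11,
    )
    return generate_cpi_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_fixture):
    return FeatureStore(
        compound=small_fixture.compound_features,
        protein=msa_features(small_fixture.identity).as_descriptor_matrix(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
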