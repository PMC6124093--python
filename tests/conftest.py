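import numpy as np
import pytest

from colonyabc import (
    DesignSpec,
    LatticeConfig,
    ModelParams,
    generate_observed_dataset,
    make_fixtures,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Miniature deterministic dataset exercising all statistic branches."""
    return make_fixtures(7)


@pytest.fixture(scope="session")
def scratch_observed():
    """Default scratch-assay observed dataset at the reference parameters."""
    return generate_observed_dataset(
        DesignSpec(seeded_rows=6, n_initial=24),
        ModelParams(0.25, 0.0025),
        LatticeConfig(),
        rng=2024,
    )
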