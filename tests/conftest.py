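import numpy as np
import pytest

from lnchcc import (
    PairedDifferentialExpression,
    demo_config,
    generate_dataset,
    quantile_normalize,
)

TEST_SEED = 7


@pytest.fixture(scope="session")
def demo_dataset():
    """The bundled synthetic study at a fixed seed."""
    return generate_dataset(demo_config(TEST_SEED))


@pytest.fixture(scope="session")
def normalized(demo_dataset):
    return quantile_normalize(demo_dataset.matrix)


@pytest.fixture(scope="session")
def fitted_de(demo_dataset, normalized):
    biotype = demo_dataset.annotation.set_index("probe_id")["biotype"]
    return PairedDifferentialExpression().fit(
        normalized, demo_dataset.design, biotype)


@pytest.fixture
def rng():
    return np.random.default_rng(TEST_SEED)
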