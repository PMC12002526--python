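import numpy as np
import pytest

from sphereinsight.synthetic_data import generate_dataset, preset_params
from sphereinsight.pipeline import tangent_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_dataset():
    """Strong-signal desk-scale dataset shared by the expensive tests."""
    table, labels, truth = generate_dataset(preset_params("desk-strong", seed=1))
    return table, labels, truth


@pytest.fixture(scope="session")
def desk_features(desk_dataset):
    table, _, _ = desk_dataset
    return tangent_features(table)
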