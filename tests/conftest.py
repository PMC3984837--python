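import numpy as np
import pytest

from p300select import ErpSpec, ProtocolSpec, PreprocSpec, generate_dataset
from p300select.preprocessing import feature_tensor, preprocess_dataset


@pytest.fixture(scope="session")
def preproc():
    return PreprocSpec()


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced montage and session length; full oddball structure."""
    return ProtocolSpec(n_channels=8, trials_per_session=50, target_fraction=0.2)


@pytest.fixture(scope="session")
def small_erp():
    """Clearly separable ERP on two informative channels."""
    return ErpSpec(informative_channels=(1, 3), amplitude=8.0, noise_sd=5.0)


@pytest.fixture(scope="session")
def small_dataset(small_protocol, small_erp):
    """600 trials x 8 channels, seeded."""
    return generate_dataset(small_protocol, small_erp, seed=1)


@pytest.fixture(scope="session")
def small_features(small_dataset, preproc):
    """(600, 8, 25) preprocessed feature tensor plus labels."""
    clean = preprocess_dataset(small_dataset, preproc)
    return feature_tensor(clean, preproc), np.asarray(small_dataset.labels)
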