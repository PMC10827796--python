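import warnings

import numpy as np
import pytest

from jawnet.config import tiny_config
from jawnet.phantom import generate_dataset, tiny_spec

warnings.filterwarnings("ignore", message=".*saturation/hue.*")


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config(seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 300x150 phantoms, two per class, fixed seed."""
    return generate_dataset(tiny_spec(seed=0))


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    from jawnet.model import build_model
    return build_model(tiny_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
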