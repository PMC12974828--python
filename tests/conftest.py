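import dataclasses

import numpy as np
import pytest

from dermprune import SyntheticSpec, build_xception, generate_dataset
from dermprune.graph import MICRO


@pytest.fixture(scope="session")
def micro_graph():
    return build_xception(MICRO)


@pytest.fixture(scope="session")
def small_imbalanced_set():
    """~160-image, 7-class imbalanced draw at 32 px (micro input size)."""
    spec = SyntheticSpec(class_counts=(60, 30, 25, 15, 12, 10, 8), image_size=32, seed=7)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def micro_64():
    return build_xception(dataclasses.replace(MICRO, input_size=64))
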