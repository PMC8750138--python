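import numpy as np
import pytest

from ramansharp import generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """The noiseless synthetic nine-peak benchmark."""
    return generate_dataset()


@pytest.fixture(scope="session")
def axis():
    return np.arange(1000, dtype=float)
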