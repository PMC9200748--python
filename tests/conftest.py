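import numpy as np
import pytest

from brightstain.data_io import preprocess
from brightstain.synthetic_data import SceneSpec, generate_field


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_fields():
    """Thirty preprocessed 64-px fields for fast training smoke tests."""
    return [preprocess(generate_field(SceneSpec(image_size=64, n_cells=2,
                                                noise_sd=0.01, seed=s)))
            for s in range(30)]
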