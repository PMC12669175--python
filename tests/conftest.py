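import numpy as np
import pytest

from msms_seg.preprocess_harmonize import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    data = rng.normal(50.0, 10.0, (12, 10, 6))
    return Volume(data, (1.0, 1.0, 2.0), "fixture")
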