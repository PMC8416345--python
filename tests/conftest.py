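import numpy as np
import pytest

import hrdquant as hq


@pytest.fixture(scope="session")
def small_phantom():
    """One 4-slice phantom with the default lesion plan."""
    spec = hq.PhantomSpec(shape=(4, 256, 256), seed=11)
    vol, mask, lesions = hq.generate_volume(spec)
    return spec, vol, mask, lesions


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
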