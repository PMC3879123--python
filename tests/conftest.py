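import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _deterministic_numpy():
    # tests that use the module-level numpy RNG stay reproducible
    np.random.seed(0)
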