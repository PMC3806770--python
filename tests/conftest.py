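import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def tiny_two_cluster_data():
    """Six 1-D observations in two tight, well-separated groups, z-scored."""
    x = np.array([-5.1, -5.0, -4.9, 4.9, 5.0, 5.1])[:, None]
    return (x - x.mean()) / x.std(ddof=1)
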