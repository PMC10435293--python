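import numpy as np
import pytest

from cnoddi.scheme import build_scheme


@pytest.fixture(scope="session")
def scheme65():
    """The two-shell study protocol: 1 b0 + 32 dirs at b=700 + 32 at b=2000."""
    return build_scheme([0, 700, 2000], [1, 32, 32], echo_time=67.0,
                        repetition_time=10_000.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
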