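import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, length: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def make_random_seq():
    return random_seq
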