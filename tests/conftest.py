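import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_noisy_read(fragment: str, rate: float, rng) -> str:
    """Inject sub/ins/del at sub:ins:del = 2:3:1 of ``rate`` (test-local,
    independent of the package's error model)."""
    bases = "ACGT"
    out = []
    for ch in fragment:
        u = rng.random()
        if u < rate * 2 / 6:
            out.append(bases[(bases.index(ch) + 1) % 4])
        elif u < rate * 5 / 6:
            out.append(ch)
            out.append(bases[rng.integers(0, 4)])
        elif u < rate:
            pass
        else:
            out.append(ch)
    return "".join(out)
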