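import numpy as np
import pytest

from mc4pred import DnaWindow


def random_window(rng: np.random.Generator, length: int = 41, wid: str = "w") -> DnaWindow:
    """A random valid window: ACGT letters with the center forced to C."""
    seq = rng.choice(list("ACGT"), size=length)
    seq[(length - 1) // 2] = "C"
    return DnaWindow(id=wid, sequence="".join(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def valid_windows(rng):
    return [random_window(rng, wid=f"w{i}") for i in range(20)]
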