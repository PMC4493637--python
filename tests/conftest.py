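import numpy as np
import pytest

from oryzaphos.dataset import Fragment, HALF_WINDOW, STANDARD_AA, WINDOW
from oryzaphos.synthetic import GeneratorSpec, generate, strong_signal_spec


def random_fragment(rng, label="negative", pid="p", pos=13, pads=0):
    """A random 25-mer fragment, optionally with leading pad symbols."""
    chars = [STANDARD_AA[c] for c in rng.integers(0, 20, WINDOW)]
    chars[HALF_WINDOW] = "STY"[rng.integers(0, 3)]
    for i in range(pads):
        chars[i] = "-"
    return Fragment("".join(chars), chars[HALF_WINDOW], pid, pos, label)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_signal_data():
    """Small strong-signal dataset for fast model-level tests."""
    return generate(strong_signal_spec(n_pos=60, n_neg=60, seed=5))


@pytest.fixture(scope="session")
def medium_signal_data():
    """Medium strong-signal dataset shared by CV-level tests."""
    return generate(strong_signal_spec(n_pos=250, n_neg=250, seed=7))
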