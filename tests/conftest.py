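import numpy as np
import pytest

from tmdscan.alphabet import StructuralAlphabet, load_alphabet
from tmdscan.builder import build_conformation


@pytest.fixture(scope="session")
def alphabet():
    return load_alphabet()


@pytest.fixture(scope="session")
def helix_state(alphabet):
    return alphabet.nearest_state(-57.0, -47.0)


@pytest.fixture(scope="session")
def extended_state(alphabet):
    return alphabet.nearest_state(-129.0, 123.0)


@pytest.fixture(scope="session")
def toy_alphabet():
    """Tiny 4-state alphabet for enumerable searches."""
    return StructuralAlphabet(np.array(
        [[-57.0, -47.0], [-129.0, 123.0], [-75.0, 145.0], [57.0, 47.0]]))


@pytest.fixture(scope="session")
def helix19(alphabet, helix_state):
    return build_conformation("L" * 19, [helix_state] * 19, alphabet)


@pytest.fixture(scope="session")
def helix19_lys(alphabet, helix_state):
    return build_conformation("K" * 19, [helix_state] * 19, alphabet)


def random_rotation(seed=0):
    from tmdscan.geometry import random_rotations

    return random_rotations(1, np.random.default_rng(seed))[0]
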