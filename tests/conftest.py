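import numpy as np
import pytest

from dsfusion import Frame, MassFunction, paradox_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return paradox_fixtures()


@pytest.fixture(scope="session")
def frame3():
    return Frame(("F", "G", "H"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masses(rng, phi, n, allow_zero=True):
    """Random valid mass vectors (rows sum to 1) for property tests."""
    raw = rng.random((n, phi))
    if allow_zero:
        raw[rng.random((n, phi)) < 0.2] = 0.0
        # keep at least one positive entry per row
        dead = raw.sum(axis=1) == 0
        raw[dead, 0] = 1.0
    return raw / raw.sum(axis=1, keepdims=True)


def as_mass_list(frame, rows):
    return [MassFunction(frame, r) for r in rows]
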