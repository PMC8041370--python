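import numpy as np
import pytest

from stereoshift.conformer import Conformer
from stereoshift.spr import LangmuirParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def nanomolar_binder():
    """ka/kd giving the ~18 nM affinity scale of the reported interaction."""
    return LangmuirParams(ka=1e5, kd=1.82e-3, rmax=100.0)


def make_conformer(coords, cid="c", energy=0.0, elements=None, shieldings=None):
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = tuple(["C"] * len(coords))
    return Conformer(cid, tuple(elements), coords, energy, shieldings)


@pytest.fixture
def make_conf():
    return make_conformer
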