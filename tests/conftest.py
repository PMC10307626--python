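import numpy as np
import pytest

from ninjfil import ScrewSymmetry, build_filament, synth_protomer
from ninjfil.synth import ProtomerSpec

NINJ_RISE = 20.95
NINJ_TWIST = -1.05


@pytest.fixture(scope="session")
def toy_protomer():
    return synth_protomer(ProtomerSpec(seed=0))


@pytest.fixture(scope="session")
def ninj_screw():
    return ScrewSymmetry(rise=NINJ_RISE, twist=NINJ_TWIST)


@pytest.fixture(scope="session")
def filament20(toy_protomer, ninj_screw):
    return build_filament(toy_protomer, ninj_screw, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
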