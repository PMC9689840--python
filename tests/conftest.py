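import numpy as np
import pytest

from limbalign.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def neutral_spec():
    """Neutral alignment: collinear mechanical axes, orthogonal joint lines."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def neutral_phantom(neutral_spec):
    return generate_phantom(neutral_spec)


@pytest.fixture(scope="session")
def varus_phantom():
    spec = PhantomSpec(knee_varus_valgus=4.0, plateau_obliquity=2.0,
                       femoral_jointline_obliquity=-1.5, ankle_obliquity=3.0,
                       seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tka_phantom():
    spec = PhantomSpec(implant="tka", knee_varus_valgus=-3.0, seed=11)
    return generate_phantom(spec)
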