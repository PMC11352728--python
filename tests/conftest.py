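import numpy as np
import pytest

from asymcat.synthetic import generate_complex_fixture


@pytest.fixture(scope="session")
def bidentate_fixture():
    """Toy [Rh(PP)(NBD)]+ complex with known ground-truth atom roles."""
    return generate_complex_fixture(arm_bulk=1, bite_angle_target=90.0, seed=3)


@pytest.fixture(scope="session")
def monodentate_fixture():
    return generate_complex_fixture(arm_bulk=0, seed=7, donors=("P",))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
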