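import numpy as np
import pytest

from hippodwi.dwisim import make_scheme
from hippodwi.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def scheme60():
    """Default acquisition: 60 directions at b=1000 s/mm^2, 6 b=0 images."""
    return make_scheme(n_dirs=60, b=1000.0, n_b0=6, seed=0)


@pytest.fixture(scope="session")
def control_phantom():
    return generate_phantom(PhantomSpec(rng_seed=0))


@pytest.fixture(scope="session")
def ipsi_phantom():
    return generate_phantom(PhantomSpec(condition="ipsilateral", rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
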