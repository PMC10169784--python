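import numpy as np
import pytest

from chdseg.matching import build_default_library
from chdseg.phantom import canonical_spec, generate_phantom


@pytest.fixture(scope="session")
def normal_case():
    """One seeded normal-anatomy phantom at the default desk scale."""
    return generate_phantom(canonical_spec("normal", seed=7, jitter=2.0))


@pytest.fixture(scope="session")
def small_case():
    """A 64-cubed phantom (1.5 mm spacing) for the cheaper net tests."""
    return generate_phantom(canonical_spec("normal", seed=3, jitter=2.0),
                            shape=(64, 64, 64), spacing=(1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def library():
    """The built-in anatomy template library (built once per session)."""
    return build_default_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
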