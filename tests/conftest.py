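import numpy as np
import pytest

from biosorb import builtin_table2
from biosorb.rsm import published_quadratic


@pytest.fixture(scope="session")
def table2():
    return builtin_table2()


@pytest.fixture(scope="session")
def study_surface():
    """The quadratic surface reported by the bundled CCD study."""
    return published_quadratic()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
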