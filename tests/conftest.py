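import numpy as np
import pytest

import assayopt as ao


@pytest.fixture(scope="session")
def reference_design():
    design, y = ao.load_design()
    return design, y


@pytest.fixture(scope="session")
def reference_fit(reference_design):
    design, y = reference_design
    return ao.ResponseSurfaceModel(design, y, transform="ln").fit()


@pytest.fixture(scope="session")
def reference_factors():
    return list(ao.REFERENCE_FACTORS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
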