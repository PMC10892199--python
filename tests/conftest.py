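import numpy as np
import pytest
from hypothesis import settings

from ecgsuperpose import generate_template

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def template():
    """Default one-cycle morphology: 180 samples, 1000 uV R peak."""
    return generate_template(180, 1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
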