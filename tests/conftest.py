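import numpy as np
import pytest

from amri.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(seed=42, subject_id="fix-a")


@pytest.fixture(scope="session")
def t1_phantom(phantom_spec):
    return make_phantom(phantom_spec, "T1")


@pytest.fixture(scope="session")
def noisefree_phantom():
    return make_phantom(
        PhantomSpec(seed=7, subject_id="fix-clean", background_sigma=0.0), "T1"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
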