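import logging

import numpy as np
import pytest

from nbackeeg import StudySpec, load_table1_fixture, table2_condition_specs

# the generator's near-Gaussian sources routinely defeat FastICA; the
# documented pass-through path logs, which would flood test output
logging.getLogger("nbackeeg.preprocess").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def default_study_spec():
    return StudySpec(seed=0)


@pytest.fixture(scope="session")
def twoback_specs():
    return table2_condition_specs(2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
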