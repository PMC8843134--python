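import numpy as np
import pytest

import fertopt as f


@pytest.fixture(scope="session")
def table1():
    return f.load_table1()


@pytest.fixture(scope="session")
def table1_reps(table1):
    return f.reconstruct_replicates(table1, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
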