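import numpy as np
import pytest

from latenteval.hmm import make_cycle_teacher, make_hmm_dataset


@pytest.fixture(scope="session")
def small_hmm_dataset():
    """A small 4-cycle teacher dataset: 80 train / 20 test trials, 20 neurons."""
    teacher = make_cycle_teacher(4, 20, 1e-2, seed=0)
    ds, states = make_hmm_dataset(teacher, s_train=80, s_test=20, T=10, n_out=10, seed=1)
    return teacher, ds, states


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
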