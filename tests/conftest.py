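import numpy as np
import pytest

from itcddm.data import standardize_attributes
from itcddm.simulate import d2_template, generate_dataset


@pytest.fixture(scope="session")
def small_synth():
    """Small within-subject synthetic study shared across test modules."""
    return generate_dataset(d2_template(n_participants=6, trials_per_session=30),
                            seed=42)


@pytest.fixture(scope="session")
def small_pp(small_synth):
    return standardize_attributes(small_synth.dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
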