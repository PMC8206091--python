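import numpy as np
import pytest

from retinerve.records import split_by_patient
from retinerve.synthetic import GeneratorConfig, generate_dataset
from retinerve.vf_geometry import build_grid


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def small_dataset():
    """120 QC-clean records with split labels (30 patients x 2 eyes x 2 tests)."""
    ds, truth = generate_dataset(GeneratorConfig(n_patients=30, seed=7))
    return split_by_patient(ds, seed=7), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
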