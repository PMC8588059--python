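import numpy as np
import pytest

from glycofit.dataset_curation import charge_statistics
from glycofit.forcefield_io import glucose_parameters
from glycofit.molecule_model import glucose_geometry, glucose_template
from glycofit.synthetic_data import GeneratorConfig, ground_truth_parameters, make_dataset


@pytest.fixture(scope="session")
def topology():
    return glucose_template()


@pytest.fixture(scope="session")
def chair_coords():
    return glucose_geometry()


@pytest.fixture(scope="session")
def start_params():
    return glucose_parameters()


@pytest.fixture(scope="session")
def truth_params():
    return ground_truth_parameters()


@pytest.fixture(scope="session")
def small_dataset():
    """Sixty noise-free synthetic conformers with oracle energies and charges."""
    return make_dataset(GeneratorConfig(n_structures=60, seed=2024))


@pytest.fixture(scope="session")
def small_charge_stats(small_dataset):
    return charge_statistics(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
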