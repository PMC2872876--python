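import numpy as np
import pytest

from phylocov import datasets, parse_species_tree


@pytest.fixture(scope="session")
def three_species_tree():
    return parse_species_tree("((A:10,B:10)AB:5,C:15)Root;")


@pytest.fixture(scope="session")
def four_species_tree():
    return parse_species_tree("((A:10,B:10)AB:5,(C:12,D:12)CD:3)Root;")


@pytest.fixture(scope="session")
def eutherian_tree():
    return datasets.eutherian_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
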