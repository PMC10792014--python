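import numpy as np
import pytest

from phylofam.datasets import example_species_tree, two_taxon_species_tree


@pytest.fixture
def species12():
    return example_species_tree()


@pytest.fixture
def species2():
    return two_taxon_species_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(918273645)
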