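import pytest

from trimerlib import thisf
from trimerlib.simulate import ErrorModel, simulate_clones


@pytest.fixture(scope="session")
def mixture():
    return thisf.standard_mixture()


@pytest.fixture(scope="session")
def scheme():
    return thisf.thisf_scheme()


@pytest.fixture(scope="session")
def cds():
    return thisf.coding_sequence()


@pytest.fixture(scope="session")
def assembly_report():
    return thisf.assemble()


@pytest.fixture(scope="session")
def clean_clones(cds, scheme):
    """400 error-free simulated clones (~10k randomized codons) with
    ground truth."""
    return simulate_clones(cds, scheme, ErrorModel.zero(), 400, seed=17)


@pytest.fixture(scope="session")
def noisy_clones(cds, scheme):
    """4000 clones under the default (observed) error rates: 104k
    randomized triplets, enough to recover the configured rates."""
    return simulate_clones(cds, scheme, ErrorModel(), 4000, seed=23)
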