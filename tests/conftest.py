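import numpy as np
import pytest

import sd1hap as s
from sd1hap.simulate import CHR1_OFFSET


@pytest.fixture(scope="session")
def config():
    return s.SimConfig(seed=7)


@pytest.fixture(scope="session")
def reference_and_model(config):
    return s.make_reference(config)


@pytest.fixture(scope="session")
def reference(reference_and_model):
    return reference_and_model[0]


@pytest.fixture(scope="session")
def gene_model(reference_and_model):
    return reference_and_model[1]


@pytest.fixture(scope="session")
def definitions():
    """Shipped haplotype table in chromosome-1 coordinates."""
    return s.load_definitions()


@pytest.fixture(scope="session")
def locus_definitions(definitions):
    """Shipped haplotype table mapped onto the synthetic locus."""
    return definitions.shifted(-CHR1_OFFSET)


@pytest.fixture(scope="session")
def small_cohort():
    """Two accessions per haplotype class plus two GR/EQ heterozygotes."""
    return s.simulate_cohort(s.SimConfig(seed=11), n_per_class=2, n_heterozygous=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
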