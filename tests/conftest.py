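import numpy as np
import pytest

from genegrad.core_model import GenomeSequence
from genegrad.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort60():
    """A small but complete synthetic cohort shared across test modules."""
    config = SimConfig(seed=11, n_genes=60)
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def flat_genome(rng):
    """A 200 kb random genome with genome-wide CpG content, single contig."""
    bases = rng.choice(list("ACGT"), size=200_000, p=[0.3, 0.2, 0.2, 0.3])
    return GenomeSequence({"chr1": "".join(bases)})
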