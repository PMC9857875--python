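import logging

import numpy as np
import pytest

from trfscape.reference import build_reference
from trfscape.simulate import generate_trna_genome

logging.getLogger("trfscape").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 20-gene genome with tRNA gene models."""
    return generate_trna_genome(seed=1, n_genes=20)


@pytest.fixture(scope="session")
def small_reference(small_genome):
    genome, genes = small_genome
    return build_reference(genes, genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
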