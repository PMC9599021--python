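import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phenodiv.datasets import load_berry_means, load_locus_reference
from phenodiv.ssr import SSRGenotypeTable


@pytest.fixture(scope="session")
def berry_means():
    return load_berry_means().set_index("genotype")


@pytest.fixture(scope="session")
def locus_reference():
    return load_locus_reference()


@pytest.fixture()
def tiny_table():
    """Two loci, four genotypes, one missing call at L2."""
    calls = np.array(
        [
            [[200, 204], [300, 300]],
            [[200, 200], [300, 306]],
            [[204, 204], [np.nan, np.nan]],
            [[200, 204], [306, 306]],
        ],
        dtype=float,
    )
    return SSRGenotypeTable(["g1", "g2", "g3", "g4"], ["L1", "L2"], calls)
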