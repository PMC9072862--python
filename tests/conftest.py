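import numpy as np
import pytest

from dhpredict import build_map, simulate_founders


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes of 1 Morgan with 10 uniformly spaced markers each."""
    return build_map(n_chrom=2, chrom_length_morgan=1.0, n_markers=20)


@pytest.fixture(scope="session")
def barley_map():
    """Default-sized genome: 7 chromosomes x 1.5 Morgan, 700 markers."""
    return build_map(n_chrom=7, chrom_length_morgan=1.5, n_markers=700)


@pytest.fixture(scope="session")
def panel(barley_map):
    """Default 5 elite + 5 donor founder panel."""
    return simulate_founders(barley_map, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
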