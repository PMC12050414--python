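import numpy as np
import pytest

from cpg_landscape.genetic_code import CodonTable


@pytest.fixture(scope="session")
def table():
    return CodonTable.standard()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
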