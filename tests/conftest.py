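import numpy as np
import pytest

from tretools.genome import GenomeSequence
from tretools.motifs import builtin_patterns


@pytest.fixture(scope="session")
def patterns():
    return builtin_patterns()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture()
def random_genome_seq(rng):
    return GenomeSequence("chrT", random_sequence(rng, 5000))
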