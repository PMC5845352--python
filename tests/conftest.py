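import numpy as np
import pytest

import fem


@pytest.fixture(scope="session")
def tiny_genome():
    return fem.ReferenceGenome([("ref", "AAAAAAAA")])


@pytest.fixture(scope="session")
def genome_10k():
    return fem.generate_genome(10_000, seed=11)


@pytest.fixture(scope="session")
def genome_20k():
    return fem.generate_genome(20_000, seed=12)


@pytest.fixture(scope="session")
def genome_50k():
    return fem.generate_genome(50_000, seed=13)


@pytest.fixture(scope="session")
def index_50k(genome_50k):
    return fem.build_index(genome_50k, k=12, l_step=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
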