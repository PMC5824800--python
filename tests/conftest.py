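import numpy as np
import pytest

from protocode.chemical_space import load_amino_acid_table
from protocode.sgc_reference import sgc_table


@pytest.fixture(scope="session")
def aa_table():
    return load_amino_acid_table()


@pytest.fixture(scope="session")
def sgc():
    return sgc_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_codon_table(rng, names, surjective=False):
    """Random total codon table; with surjective=True all names appear."""
    n = len(names)
    assign = rng.integers(0, n, size=64)
    if surjective:
        assign[:n] = rng.permutation(n)
        assign = rng.permutation(assign)
    from protocode.codon_space import CodonTable

    return CodonTable(assign, tuple(names))
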