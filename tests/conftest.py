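import numpy as np
import pytest

from slopespam import NucleotideSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genome(rng):
    """Factory for random genomes, optionally with N residues."""

    bases = np.array(list("ACGTN"))

    def make(name: str, length: int, n_frac: float = 0.0) -> NucleotideSequence:
        probs = [(1 - n_frac) / 4] * 4 + [n_frac]
        return NucleotideSequence(name, ["".join(rng.choice(bases, length, p=probs))])

    return make
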