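import numpy as np
import pytest

from mdachimera import GenomeReference


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(length: int, rng: np.random.Generator, n_run: int = 0) -> str:
    """Plain random ACGT string, optionally with one N run in the middle."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
    if n_run:
        mid = length // 2
        seq = seq[:mid] + "N" * n_run + seq[mid + n_run :]
    return seq


@pytest.fixture
def small_genome(rng):
    """Single 20-knt chromosome of i.i.d. uniform bases."""
    return GenomeReference({"chr1": random_sequence(20_000, rng)})
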