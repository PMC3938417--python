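import numpy as np
import pandas as pd
import pytest

from haplodrift import Alignment, HaplotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20140228)


@pytest.fixture
def toy_alignment():
    """Four 10-bp sequences, two populations, two segregating sites."""
    seqs = [
        "ACGTACGTAC",
        "ACGTACGTAC",
        "ACGTACGTAT",  # differs at site 10
        "ACGAACGTAC",  # differs at site 4
    ]
    from haplodrift.alignment import encode_sequence

    matrix = np.stack([encode_sequence(s) for s in seqs])
    return Alignment(
        ["s1", "s2", "s3", "s4"],
        ["popA", "popA", "popA", "popA"],
        matrix,
    )


@pytest.fixture
def two_pop_table():
    counts = pd.DataFrame(
        {"popA": [8, 2, 0], "popB": [1, 4, 5]},
        index=["H1", "H2", "H3"],
    )
    return HaplotypeTable(counts)


def random_alignment(rng, n, L, n_states=4):
    """A random base-coded alignment (no missing data)."""
    matrix = rng.integers(0, n_states, size=(n, L)).astype(np.uint8)
    ids = [f"s{i}" for i in range(n)]
    return Alignment(ids, ["pop"] * n, matrix)
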