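import numpy as np
import pytest

from rnaloopkit.motifs import generate_random_structure
from rnaloopkit.structio import SecondaryStructure


@pytest.fixture
def random_structures():
    """Factory: n seeded random nested structures in a length range."""

    def make(n, min_len=20, max_len=200, seed=0, **kwargs):
        rng = np.random.default_rng(seed)
        out = []
        for k in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            out.append(
                generate_random_structure(length, seed=int(rng.integers(2**31)), **kwargs)
            )
        return out

    return make


@pytest.fixture
def random_pair_sets():
    """Factory: random (possibly crossing) pair sets as SecondaryStructures."""

    def make(n, max_pairs=10, length=40, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            n_pairs = int(rng.integers(1, max_pairs + 1))
            positions = rng.choice(length, size=2 * n_pairs, replace=False)
            rng.shuffle(positions)
            pairs = set()
            for k in range(n_pairs):
                i, j = sorted(positions[2 * k : 2 * k + 2] + 1)
                pairs.add((int(i), int(j)))
            out.append(SecondaryStructure(length, frozenset(pairs)))
        return out

    return make


THE_24NT_JUNCTION_DB = "((..((...))..((...))..))"
THE_24NT_JUNCTION_SEQ = "GGAAGGAAACCAAGGAAACCAACC"


@pytest.fixture
def junction_example():
    """The 24-nt 3-way junction with two hairpin arms used across tests."""
    from rnaloopkit.structio import parse_dotbracket

    ss = parse_dotbracket(THE_24NT_JUNCTION_DB)
    return SecondaryStructure(ss.length, ss.pairs, THE_24NT_JUNCTION_SEQ)
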