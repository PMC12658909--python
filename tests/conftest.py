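import numpy as np
import pytest

from seascapegen.genotypes import MISSING, GenotypeMatrix
from seascapegen.simulate import PopSpec, simulate_ancestral_frequencies, simulate_genotypes


def make_matrix(calls, pops, locus_prefix="L"):
    """Small GenotypeMatrix from a nested list and per-individual pop codes."""
    calls = np.asarray(calls, dtype=np.int16)
    n, L = calls.shape
    ids = [f"{pops[i]}_{i + 1}" for i in range(n)]
    return GenotypeMatrix(calls, ids, np.asarray(pops, dtype=object),
                          [f"{locus_prefix}{j + 1}" for j in range(L)])


@pytest.fixture
def tiny_two_pop():
    """4 individuals, 2 loci, 2 populations; no missing data."""
    return make_matrix([[0, 1], [1, 1], [2, 0], [2, 2]], ["A", "A", "B", "B"])


@pytest.fixture
def opposite_fixed():
    """Two populations fixed for opposite alleles at every locus."""
    calls = np.vstack([np.zeros((20, 5)), np.full((20, 5), 2)])
    return make_matrix(calls, ["A"] * 20 + ["B"] * 20)


@pytest.fixture(scope="session")
def diverged_pair():
    """Two pure lineages at divergence F=0.3 (n=100 each, 300 loci)."""
    freqs = simulate_ancestral_frequencies(300, 0.3, seed=11)
    G, truth = simulate_genotypes(
        freqs, [PopSpec("A", 100, 1.0), PopSpec("B", 100, 0.0)], seed=12)
    return G, truth, freqs
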