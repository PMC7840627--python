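import numpy as np
import pytest

from comphet.io_formats import GenotypeMatrix
from comphet.synthetic_data import (FlockConfig, encode_fig2a_fixture,
                                    make_funnel_fixture, make_toy_genes,
                                    simulate_flock)


@pytest.fixture(scope="session")
def toys():
    return make_toy_genes(seed=0)


@pytest.fixture(scope="session")
def fig2a():
    return encode_fig2a_fixture()


@pytest.fixture(scope="session")
def funnel_fixture():
    return make_funnel_fixture(seed=0)


@pytest.fixture(scope="session")
def flock():
    """One default compound-het study flock shared across read-only tests."""
    return simulate_flock(FlockConfig(seed=1))


@pytest.fixture(scope="session")
def recessive_flock():
    return simulate_flock(FlockConfig(seed=2, mode="recessive",
                                      n_array_markers=20000))


def random_genotype_matrix(seed: int, n_samples: int = 12,
                           n_markers: int = 40) -> GenotypeMatrix:
    """Random matrix whose first rows pin all three states at every marker,
    so PED allele inference is unambiguous on a round trip."""
    rng = np.random.default_rng(seed)
    calls = rng.choice([-1, 0, 1, 2], size=(n_samples, n_markers),
                       p=[0.05, 0.35, 0.3, 0.3]).astype(np.int8)
    calls[0] = 0
    calls[1] = 1
    calls[2] = 2
    chroms = np.repeat(["1", "2"], n_markers // 2).astype(object)
    pos = np.concatenate([np.sort(rng.choice(10_000_000, n_markers // 2,
                                             replace=False))
                          for _ in range(2)])
    bases = ["A", "C", "G", "T"]
    alleles = []
    for _ in range(n_markers):
        a, b = rng.choice(4, size=2, replace=False)
        # allele1/allele2 in the reader's canonical (lexicographic) order,
        # so the four-state encoding survives a write/read cycle
        alleles.append(tuple(sorted((bases[a], bases[b]))))
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        marker_ids=[f"M{j}" for j in range(n_markers)],
        chrom=chroms, pos=pos, calls=calls, alleles=alleles)
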