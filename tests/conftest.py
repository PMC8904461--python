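import numpy as np
import pytest

from ssrid.genotype_io import MISSING, GenotypeMatrix


def build_matrix(rows, populations=None, locus_ids=None, individual_ids=None):
    """Build a GenotypeMatrix from a list (per individual) of allele pairs.

    ``rows[i][j]`` is ``(a, b)`` or ``None`` for a missing call.
    """
    n_ind = len(rows)
    n_loci = len(rows[0])
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell is not None:
                calls[i, j] = cell
    if populations is None:
        populations = ["P1"] * n_ind
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    if individual_ids is None:
        individual_ids = [f"I{i + 1}" for i in range(n_ind)]
    return GenotypeMatrix(individual_ids, locus_ids, populations, calls)


@pytest.fixture
def toy_matrix():
    """3 individuals, 2 loci, 1 population; one heterozygote at L1."""
    return build_matrix(
        [
            [(100, 100), (1, 1)],
            [(100, 102), (1, 2)],
            [(102, 102), (2, 2)],
        ]
    )


@pytest.fixture
def two_pop_matrix():
    """Two populations of 3, disjoint allele sets at both loci."""
    return build_matrix(
        [
            [(100, 100), (10, 12)],
            [(100, 102), (10, 10)],
            [(102, 102), (12, 12)],
            [(200, 200), (20, 22)],
            [(200, 202), (20, 20)],
            [(202, 202), (22, 22)],
        ],
        populations=["A", "A", "A", "B", "B", "B"],
    )
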