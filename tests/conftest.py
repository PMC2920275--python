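import numpy as np
import pytest

from mdrsplit import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20231102)


@pytest.fixture
def noise_dataset(rng):
    """60 individuals x 6 loci with no genotype-phenotype association."""
    genotypes = rng.integers(0, 3, size=(60, 6))
    phenotype = np.repeat([1, 0], 30)
    return GenotypeDataset(phenotype=phenotype, genotypes=genotypes)


@pytest.fixture
def perfect_pair_dataset(rng):
    """Loci (2, 5) determine the phenotype through an XOR-parity rule.

    Every other locus is noise, so the pair is a perfect two-locus
    predictor while neither member has full single-locus accuracy.
    """
    n = 200
    genotypes = rng.integers(0, 3, size=(n, 8))
    phenotype = ((genotypes[:, 2] + genotypes[:, 5]) % 2 == 1).astype(int)
    # guarantee both classes present
    phenotype[0], phenotype[1] = 1, 0
    genotypes[0, 2], genotypes[0, 5] = 0, 1
    genotypes[1, 2], genotypes[1, 5] = 0, 0
    return GenotypeDataset(phenotype=phenotype, genotypes=genotypes)


def brute_force_best(data, k):
    """Independent MDR oracle: hash-map cell tabulation, full enumeration.

    Returns (loci, ba) maximizing balanced accuracy with lexicographic
    tie-breaking; shares no code with the vectorized implementation.
    """
    import itertools

    n1 = int(data.phenotype.sum())
    n0 = data.n - n1
    best = None
    for loci in itertools.combinations(range(data.n_loci), k):
        cells = {}
        for row, y in zip(data.genotypes, data.phenotype):
            key = tuple(int(row[j]) for j in loci)
            a, b = cells.get(key, (0, 0))
            cells[key] = (a + int(y), b + 1 - int(y))
        n11 = sum(a for a, b in cells.values() if a * n0 > b * n1)
        n00 = sum(b for a, b in cells.values() if not a * n0 > b * n1)
        ba = 0.5 * (n11 / n1 + n00 / n0)
        if best is None or ba > best[1]:
            best = (loci, ba)
    return best
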