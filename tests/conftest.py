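import numpy as np
import pytest

from aimkit.core_io import FrequencyTable, GenotypeMatrix, PanelSnp


def make_panel(n_loci, alleles=("A", "G"), seed=None):
    """A simple biallelic panel of n_loci markers."""
    return [
        PanelSnp(snp_id=f"rs{i:04d}", chromosome="1", position=100 + i, alleles=alleles)
        for i in range(n_loci)
    ]


def random_matrix(n_samples, n_loci, rng, missing_rate=0.05, n_pops=3):
    """A random GenotypeMatrix over biallelic A/G loci with some MISSING cells."""
    loci = make_panel(n_loci)
    pops = [f"POP{k}" for k in range(n_pops)]
    labels = [pops[rng.integers(n_pops)] for _ in range(n_samples)]
    flags = [int(rng.random() < 0.8) for _ in range(n_samples)]
    genos = ["AA", "AG", "GG"]
    calls = np.empty((n_samples, n_loci), dtype=object)
    for i in range(n_samples):
        for j in range(n_loci):
            if rng.random() < missing_rate:
                calls[i, j] = None
            else:
                calls[i, j] = genos[rng.integers(3)]
    return GenotypeMatrix([f"S{i:03d}" for i in range(n_samples)], labels, flags, loci, calls)


def two_pop_table(p1, p2, n_loci=1):
    """FrequencyTable with two populations at the given A-allele frequencies."""
    loci = make_panel(n_loci)
    freqs = [np.array([[p1, 1 - p1], [p2, 1 - p2]]) for _ in range(n_loci)]
    return FrequencyTable(loci, ["P1", "P2"], freqs, np.zeros((n_loci, 2)))


@pytest.fixture
def rng():
    return np.random.default_rng(20210822)
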