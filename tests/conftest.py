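import numpy as np
import pandas as pd
import pytest

from pleioscan.grid import WindowGrid
from pleioscan.simulate import SimConfig


@pytest.fixture
def small_grid():
    """Two chromosomes of 10 windows each (50-kb windows)."""
    return WindowGrid.from_chrom_sizes({"chr1": 500_000, "chr2": 500_000})


@pytest.fixture
def tiny_config():
    """A fast simulation: 3 pairs, 100 windows, small expression matrix."""
    return SimConfig(
        n_pairs=3,
        n_diploids_per_population=20,
        n_chromosomes=2,
        chromosome_length=2_500_000,
        snps_per_window=4,
        n_genes=300,
        n_samples=20,
        n_modules=10,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genotype_counts(rng, n, max_diploids=30):
    """Random biallelic genotype counts for two populations, n sites."""
    sizes = rng.integers(2, max_diploids, size=(n, 2))
    rows1, rows2 = [], []
    for n1, n2 in sizes:
        p1, p2 = rng.uniform(0.02, 0.98, size=2)
        g1 = rng.multinomial(n1, [p1**2, 2 * p1 * (1 - p1), (1 - p1) ** 2])
        g2 = rng.multinomial(n2, [p2**2, 2 * p2 * (1 - p2), (1 - p2) ** 2])
        rows1.append(g1)
        rows2.append(g2)
    return np.array(rows1), np.array(rows2)
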