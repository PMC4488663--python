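import logging

import numpy as np
import pandas as pd
import pytest

from permgsa.datatypes import GenotypeDataset

logging.getLogger("permgsa").setLevel(logging.ERROR)


def make_dataset(genotypes, phenotype=None, binary=False, chrom="1", positions=None):
    """Build a GenotypeDataset from a raw matrix for tests."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, S = G.shape
    if phenotype is None:
        phenotype = np.full(n, np.nan)
    if positions is None:
        positions = 1 + 1000 * np.arange(S)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(S)],
            "chrom": chrom,
            "pos_bp": positions,
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "phenotype": np.asarray(phenotype, dtype=float),
        }
    )
    return GenotypeDataset(samples=samples, snps=snps, genotypes=G, binary_trait=binary)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_quantitative(rng):
    """60 samples x 12 SNPs with a quantitative phenotype, some missing calls."""
    G = rng.integers(0, 3, size=(60, 12)).astype(np.int8)
    G[rng.random((60, 12)) < 0.05] = -1
    y = rng.standard_normal(60)
    return make_dataset(G, y)
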