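import numpy as np
import pandas as pd
import pytest

from ailrep import simdata
from ailrep.core import GenotypeMatrix


@pytest.fixture(scope="session")
def ail_pedigree():
    return simdata.build_ail_pedigree(12, 5, 4, seed=7)


@pytest.fixture(scope="session")
def genetic_map():
    return simdata.make_genetic_map(
        n_chrom=2, snps_per_chrom=30, chrom_length_cm=60.0, seed=11,
        albino_proxy=True, agouti_proxy=True,
    )


@pytest.fixture(scope="session")
def ail_genotypes(ail_pedigree, genetic_map):
    return simdata.gene_drop(ail_pedigree, genetic_map, seed=13)


@pytest.fixture(scope="session")
def ail_kinship(ail_pedigree):
    return simdata.kinship_from_pedigree(ail_pedigree)


def make_genotypes(dosages, chrom="1", pos=None, snp_ids=None, **map_cols):
    """Hand-built genotype matrix from a (samples x SNPs) array."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if pos is None:
        pos = [1000 * (k + 1) for k in range(m)]
    if snp_ids is None:
        snp_ids = [f"s{k}" for k in range(m)]
    snp_map = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
         "pos": pos, **map_cols}
    )
    samples = [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, snp_map, samples)


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(5)
    return make_genotypes(rng.integers(0, 3, size=(60, 12)).astype(float))
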