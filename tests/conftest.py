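import numpy as np
import pytest

from stsbn.data import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_noise_matrix(rng, n=2000, m=100, maf_range=(0.05, 0.5)) -> GenotypeMatrix:
    """Pure-noise case-control matrix: markers independent of the phenotype."""
    mafs = rng.uniform(*maf_range, size=m)
    geno = rng.binomial(2, mafs[None, :].repeat(n, axis=0)).astype(np.int8)
    pheno = np.zeros(n, dtype=np.int8)
    pheno[: n // 2] = 1
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=pheno,
        marker_ids=[f"m{j}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def noise_matrix(rng):
    return make_noise_matrix(rng)
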