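import numpy as np
import pytest

from poda.io import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_genotypes(n_samples, n_snps, seed, maf_low=0.1, maf_high=0.4, missing=0.0):
    """Small random HWE genotype matrix with labels independent of genotype."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, n_snps)
    values = rng.binomial(2, mafs, size=(n_samples, n_snps)) / 2.0
    if missing:
        mask = rng.random(values.shape) < missing
        values[mask] = np.nan
    samples = [f"S{i:03d}" for i in range(n_samples)]
    snps = [f"rs{j:04d}" for j in range(n_snps)]
    gm = GenotypeMatrix(samples, snps, values)
    n_cases = n_samples // 2
    labels = np.zeros(n_samples, dtype=bool)
    labels[:n_cases] = True
    return gm, PhenotypeVector(samples, labels)


@pytest.fixture
def small_gwas():
    return random_genotypes(30, 12, seed=42)
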