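import numpy as np
import pytest

import famassoc as fa


@pytest.fixture(scope="session")
def small_cfg():
    return fa.SimConfig(n_families=4, family_size_mean=20, n_snps=40,
                        block_size=8, seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """~90-individual, 40-SNP family dataset shared across tests."""
    ped = fa.simulate_pedigree(small_cfg)
    geno = fa.gene_drop(ped, small_cfg)
    return ped, geno


@pytest.fixture(scope="session")
def small_K(small_data):
    _, geno = small_data
    return fa.repair_psd(fa.rrm(geno))


@pytest.fixture(scope="session")
def family_null_machine():
    """Reusable generator of null traits on a fixed family structure.

    Returns (pedigree, genotypes, K2phi, draw) where draw(rng, h2, n_traits)
    yields traits with polygenic covariance h2 * 2*Phi and residual 1 - h2,
    exactly matching the kinship handed to the solver (well-specified null).
    """
    cfg = fa.SimConfig(n_families=4, family_size_mean=48, n_snps=60,
                       block_size=10, seed=202)
    ped = fa.simulate_pedigree(cfg)
    geno = fa.gene_drop(ped, cfg)
    K2 = 2.0 * fa.pedigree_kinship(ped)
    n = K2.shape[0]
    L = np.linalg.cholesky(K2 + 1e-10 * np.eye(n))

    def draw(rng, h2, n_traits=1):
        g = np.sqrt(h2) * (L @ rng.standard_normal((n, n_traits)))
        e = np.sqrt(1.0 - h2) * rng.standard_normal((n, n_traits))
        return g + e

    return ped, geno, K2, draw
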